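"""Two-PCR zygosity genotyping and segregation analysis.

Each plant x locus assay combines a T-DNA-anchored PCR ("A": one genomic
primer plus one transgene primer, positive only if the junction is present)
with a T-DNA-flanking PCR ("B": two genomic primers across the insertion
point, positive only if an insertion-free native allele exists, the full
T-DNA being too long to amplify). The A/B result pair is a complete
genotype: +/+ heterozygous, +/- homozygous, -/+ wildtype null segregant,
-/- assay failure. Per-locus summaries report counts, percentages on both
the carrier and the all-plants denominator, and an optional chi-square
goodness-of-fit against the 2:1:1 het:hmz:null expectation for the selfed
progeny of a hemizygote.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

GENOTYPES = ("heterozygous", "homozygous", "wildtype_null", "indeterminate")

_SYMBOLS = {"+", "-"}

_TRUTH_TABLE = {
    ("+", "+"): "heterozygous",
    ("+", "-"): "homozygous",
    ("-", "+"): "wildtype_null",
    ("-", "-"): "indeterminate",
}


@dataclass(frozen=True)
class PcrResult:
    plant_id: str
    locus_id: str
    A: str  # T-DNA anchored PCR
    B: str  # T-DNA flanking PCR

    def __post_init__(self):
        if self.A not in _SYMBOLS or self.B not in _SYMBOLS:
            raise ValueError(f"PCR symbols must be '+' or '-', got A={self.A!r} B={self.B!r}")


@dataclass(frozen=True)
class ZygosityCall:
    plant_id: str
    locus_id: str
    genotype: str


def call_zygosity(A: str, B: str) -> str:
    """Genotype from the anchored (A) / flanking (B) PCR result pair.

    (+,+) heterozygous; (+,-) homozygous; (-,+) wildtype null segregant;
    (-,-) indeterminate (assay failure — neither allele amplified).
    """
    A = _normalise_symbol(A)
    B = _normalise_symbol(B)
    return _TRUTH_TABLE[(A, B)]


def _normalise_symbol(sym: str) -> str:
    sym = str(sym).strip()
    # tolerate unicode minus/en-dash variants from transcribed sheets
    if sym in {"−", "–", "—"}:
        sym = "-"
    if sym not in _SYMBOLS:
        raise ValueError(f"PCR result symbol must be '+' or '-', got {sym!r}")
    return sym


@dataclass
class SegregationSummary:
    locus_id: str
    counts: dict[str, int]
    n_typed: int  # plants with an interpretable (non -/-) result
    n_carriers: int  # het + hmz
    pct_of_carriers: dict[str, float]
    pct_of_typed: dict[str, float]
    table4_style: dict[str, float]  # all categories on the carrier denominator
    chi_square: float | None
    p_value: float | None
    expected_ratio: tuple[float, float, float]
    non_mendelian: bool = False


def summarize_segregation(
    results: Sequence[PcrResult],
    expected_ratio: tuple[float, float, float] = (2.0, 1.0, 1.0),
    alpha: float = 0.05,
) -> SegregationSummary:
    """Summarise one locus's T2 genotype counts and segregation.

    ``expected_ratio`` is het:hmz:null, defaulting to the 2:1:1 expectation
    among transgene-selected selfed progeny of a hemizygote. Indeterminate
    (-/-) plants are excluded from percentages and from the chi-square test.
    The carrier-denominator percentages are additionally reported for every
    category ("table4_style"), the convention of published zygosity screens
    that express even the null fraction relative to carriers.
    """
    if not results:
        raise ValueError("no PCR results supplied")
    loci = {r.locus_id for r in results}
    if len(loci) != 1:
        raise ValueError(f"summarize_segregation expects one locus, got {sorted(loci)}")
    locus_id = results[0].locus_id
    counts = {g: 0 for g in GENOTYPES}
    for r in results:
        counts[call_zygosity(r.A, r.B)] += 1
    n_typed = sum(counts[g] for g in GENOTYPES[:3])
    if n_typed == 0:
        raise ValueError(f"locus {locus_id}: zero interpretable results")
    n_carriers = counts["heterozygous"] + counts["homozygous"]
    observed = [counts["heterozygous"], counts["homozygous"], counts["wildtype_null"]]

    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 2) if den else float("nan")

    pct_carriers = {
        "heterozygous": pct(counts["heterozygous"], n_carriers),
        "homozygous": pct(counts["homozygous"], n_carriers),
    }
    pct_typed = {g: pct(counts[g], n_typed) for g in GENOTYPES[:3]}
    table4 = {g: pct(counts[g], n_carriers) for g in GENOTYPES[:3]}

    chi = p = None
    non_mendelian = False
    ratio_sum = sum(expected_ratio)
    expected = [n_typed * r / ratio_sum for r in expected_ratio]
    if all(e > 0 for e in expected):
        chi_res = stats.chisquare(observed, expected)
        chi, p = float(chi_res.statistic), float(chi_res.pvalue)
        non_mendelian = p < alpha
    return SegregationSummary(
        locus_id=locus_id,
        counts=counts,
        n_typed=n_typed,
        n_carriers=n_carriers,
        pct_of_carriers=pct_carriers,
        pct_of_typed=pct_typed,
        table4_style=table4,
        chi_square=chi,
        p_value=p,
        expected_ratio=tuple(expected_ratio),
        non_mendelian=non_mendelian,
    )


def stacking_homozygosity_prob(k: int) -> float:
    """Percent of selfed progeny homozygous at all of k independent
    hemizygous loci under Mendelian segregation: (1/4)^k * 100."""
    if k < 0:
        raise ValueError("number of loci must be non-negative")
    return 100.0 * 0.25**k


def read_genotype_sheet(path: str | Path) -> list[PcrResult]:
    """Parse a genotype sheet TSV (plant_id, locus_id, pcrA, pcrB);
    malformed rows are reported with their line number."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"plant_id", "locus_id", "pcrA", "pcrB"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype sheet must have columns {sorted(required)}")
    results = []
    for i, row in df.iterrows():
        try:
            results.append(
                PcrResult(
                    plant_id=str(row["plant_id"]),
                    locus_id=str(row["locus_id"]),
                    A=_normalise_symbol(row["pcrA"]),
                    B=_normalise_symbol(row["pcrB"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"genotype sheet line {i + 2}: {exc}") from exc
    return results


def calls_frame(results: Sequence[PcrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": r.plant_id,
                "locus_id": r.locus_id,
                "pcrA": r.A,
                "pcrB": r.B,
                "genotype": call_zygosity(r.A, r.B),
            }
            for r in results
        ]
    )


def summary_frame(summaries: Sequence[SegregationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": s.locus_id,
                "n_typed": s.n_typed,
                "n_carriers": s.n_carriers,
                "het": s.counts["heterozygous"],
                "hmz": s.counts["homozygous"],
                "wt_null": s.counts["wildtype_null"],
                "indeterminate": s.counts["indeterminate"],
                "het_pct_carriers": s.pct_of_carriers["heterozygous"],
                "hmz_pct_carriers": s.pct_of_carriers["homozygous"],
                "wt_pct_carriers": s.table4_style["wildtype_null"],
                "het_pct_typed": s.pct_of_typed["heterozygous"],
                "hmz_pct_typed": s.pct_of_typed["homozygous"],
                "wt_pct_typed": s.pct_of_typed["wildtype_null"],
                "chi_square": s.chi_square,
                "p_value": s.p_value,
                "non_mendelian": s.non_mendelian,
            }
            for s in summaries
        ]
    )
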