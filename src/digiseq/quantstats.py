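"""Quantification statistics for UMI-corrected amplicon sequencing.

Implements the standard read-level accuracy and yield metrics of digital
sequencing: per-position error rates (non-reference fraction), assay and
panel mean error rates, the raw/consensus error-correction factor, strand-
aware consensus-to-molecule conversion, input-mass normalization, replicate
CV, mutant allele frequency (MAF) estimation with t-test / two-way-ANOVA
significance, error typing (transition / transversion / deletion /
insertion), Spearman error-profile correlation, dilution linearity, and
per-mL plasma normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pileup import BASE_COLUMNS, CountMatrix
from .simulate import DOUBLE, SINGLE

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# error rates


@dataclass
class PositionErrorRates:
    """Per-position non-reference fractions for one assay and read level."""

    assay: str
    level: str
    e_p: np.ndarray  # NaN where excluded or zero coverage
    included: np.ndarray  # bool mask
    excluded_positions: frozenset[int]
    zero_coverage_positions: frozenset[int]

    @property
    def included_rates(self) -> np.ndarray:
        return self.e_p[self.included]

    @property
    def mean(self) -> float:
        rates = self.included_rates
        return float(rates.mean()) if rates.size else float("nan")


def position_error_rates(
    matrix: CountMatrix, exclusions: Iterable[int] = ()
) -> PositionErrorRates:
    """e_p = (coverage - reference count + insertions) / coverage.

    Insertions are counted as non-reference events at their left-anchor
    position (keeping the denominator equal to coverage); excluded or
    zero-coverage positions are omitted from the report and flagged.
    """
    excl = frozenset(int(p) for p in exclusions)
    cov = matrix.coverage.astype(float)
    nonref = cov - matrix.ref_counts + matrix.insertions
    with np.errstate(invalid="ignore", divide="ignore"):
        e_p = np.where(cov > 0, np.clip(nonref, 0, None) / np.where(cov > 0, cov, 1), np.nan)
    e_p = np.minimum(e_p, 1.0)
    zero = frozenset(int(i) for i in np.nonzero(cov == 0)[0])
    included = np.ones(len(matrix), dtype=bool)
    for p in excl | zero:
        included[p] = False
    e_p[~included] = np.nan
    return PositionErrorRates(
        matrix.assay_name, matrix.level, e_p, included, excl, zero
    )


def mean_error_rate(
    reports: PositionErrorRates | Sequence[PositionErrorRates],
) -> float:
    """Unweighted mean of e_p over included positions (assay or panel scope).

    Pass one report for an assay mean or several for the panel mean. Returns
    NaN when no positions are included (undefined, flagged by NaN).
    """
    if isinstance(reports, PositionErrorRates):
        reports = [reports]
    rates = np.concatenate([r.included_rates for r in reports]) if reports else np.array([])
    return float(rates.mean()) if rates.size else float("nan")


@dataclass(frozen=True)
class CorrectionFactor:
    """Ratio of mean raw to mean consensus error rate; undefined if the
    consensus mean is zero (no errors detected after correction)."""

    value: float | None
    defined: bool

    def __float__(self) -> float:
        return self.value if self.defined else float("nan")


def error_correction_factor(
    raw_mean: float, consensus_mean: float
) -> CorrectionFactor:
    if math.isnan(raw_mean) or math.isnan(consensus_mean) or consensus_mean <= 0.0:
        return CorrectionFactor(None, False)
    return CorrectionFactor(raw_mean / consensus_mean, True)


@dataclass
class ErrorReport:
    """Error rates of one read level across a panel."""

    level: str
    per_assay: dict[str, PositionErrorRates]
    assay_means: dict[str, float]
    panel_mean: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for assay, rep in self.per_assay.items():
            for i, e in enumerate(rep.e_p):
                rows.append(
                    {
                        "assay": assay,
                        "level": self.level,
                        "pos": i + 1,
                        "error_rate": e,
                        "included": bool(rep.included[i]),
                    }
                )
        return pd.DataFrame(rows)


def error_report(
    matrices: Mapping[str, CountMatrix],
    exclusions: Mapping[str, Iterable[int]] | None = None,
) -> ErrorReport:
    """Panel-wide error report; panel mean is unweighted over all included
    positions of all assays."""
    exclusions = exclusions or {}
    per_assay = {
        name: position_error_rates(m, exclusions.get(name, ()))
        for name, m in matrices.items()
    }
    levels = {m.level for m in matrices.values()}
    level = levels.pop() if len(levels) == 1 else "mixed"
    return ErrorReport(
        level=level,
        per_assay=per_assay,
        assay_means={name: rep.mean for name, rep in per_assay.items()},
        panel_mean=mean_error_rate(list(per_assay.values())),
    )


# ---------------------------------------------------------------------------
# molecule counting and yields


def consensus_to_molecules(consensus_count: float, strandedness: str) -> float:
    """One consensus read per cDNA molecule; two per genomic DNA molecule."""
    if consensus_count < 0:
        raise ValueError("consensus count must be >= 0")
    if strandedness == SINGLE:
        return float(consensus_count)
    if strandedness == DOUBLE:
        return consensus_count / 2.0
    raise ValueError(f"unknown strandedness {strandedness!r}")


def molecules_to_consensus(molecules: float, strandedness: str) -> float:
    """Inverse of :func:`consensus_to_molecules`."""
    if molecules < 0:
        raise ValueError("molecule count must be >= 0")
    if strandedness == SINGLE:
        return float(molecules)
    if strandedness == DOUBLE:
        return molecules * 2.0
    raise ValueError(f"unknown strandedness {strandedness!r}")


def normalize_yield(count: float, loaded_ng: float, reference_ng: float) -> float:
    """Scale a yield to a reference input mass (e.g. 50 ng -> 200 ng is x4)."""
    if loaded_ng <= 0:
        raise ValueError("loaded_ng must be > 0")
    return count * reference_ng / loaded_ng


@dataclass(frozen=True)
class YieldRecord:
    """Consensus-read yield of one assay/condition with molecule conversion."""

    assay: str
    condition: str
    consensus_reads: int
    strandedness: str
    loaded_ng: float = 1.0
    reference_ng: float = 1.0

    @property
    def molecules(self) -> float:
        return consensus_to_molecules(self.consensus_reads, self.strandedness)

    @property
    def scale(self) -> float:
        return self.reference_ng / self.loaded_ng

    @property
    def normalized_molecules(self) -> float:
        return normalize_yield(self.molecules, self.loaded_ng, self.reference_ng)


def replicate_cv(counts: Sequence[float]) -> float:
    """Coefficient of variation in percent (sample SD / mean * 100).

    NaN for fewer than two replicates or zero mean.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2 or arr.mean() == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / arr.mean())


# ---------------------------------------------------------------------------
# variant calling


@dataclass
class VariantCall:
    assay: str
    position: int
    alt: str
    alt_count: int
    coverage: int
    maf: float  # fraction in [0, 1]
    statistic: float | None = None
    pvalue: float | None = None
    design: str | None = None


def estimate_maf(matrix: CountMatrix, position: int, alt: str) -> VariantCall:
    """MAF = alt count / coverage at one position of a consensus matrix."""
    cov = int(matrix.coverage[position])
    if cov == 0:
        raise ValueError(f"zero coverage at position {position}")
    col = BASE_COLUMNS.index(alt) if alt in BASE_COLUMNS else None
    if col is None:
        raise ValueError(f"alt must be one of {BASE_COLUMNS}")
    alt_count = int(matrix.counts[position, col])
    return VariantCall(
        matrix.assay_name, position, alt, alt_count, cov, alt_count / cov
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def test_variant(
    case: Sequence[float], control: Sequence[float]
) -> TestResult:
    """Unpaired two-sample Student's t-test on replicate MAFs.

    Degenerate all-identical arms are flagged and returned with p = 1
    instead of crashing.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need >= 2 replicates per arm")
    if case.std() == 0 and control.std() == 0:
        if case.mean() == control.mean():
            return TestResult(0.0, 1.0, degenerate=True)
        return TestResult(float("inf"), 0.0, degenerate=True)
    t, p = sps.ttest_ind(case, control, equal_var=True)
    return TestResult(float(t), float(p))


def anova_sidak(
    data: Mapping[int, tuple[Sequence[float], Sequence[float]]]
) -> pd.DataFrame:
    """Two-way ANOVA (position x condition) with Šidák-corrected
    per-position case-vs-control comparisons.

    ``data`` maps position -> (case replicate values, control replicate
    values). Returns a per-position table with the contrast t, raw p and
    Šidák-adjusted p (1 - (1-p)^n_positions), mirroring panel-wide
    mutation screening across positions.
    """
    positions = sorted(data)
    n_pos = len(positions)
    resid_ss = 0.0
    resid_df = 0
    for pos in positions:
        for arm in data[pos]:
            arr = np.asarray(arm, dtype=float)
            resid_ss += float(((arr - arr.mean()) ** 2).sum())
            resid_df += arr.size - 1
    mse = resid_ss / resid_df if resid_df else float("nan")
    rows = []
    for pos in positions:
        case = np.asarray(data[pos][0], dtype=float)
        ctrl = np.asarray(data[pos][1], dtype=float)
        se = math.sqrt(mse * (1 / case.size + 1 / ctrl.size)) if mse > 0 else 0.0
        diff = case.mean() - ctrl.mean()
        if se > 0:
            t = diff / se
            p = 2 * sps.t.sf(abs(t), resid_df)
        else:
            t = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
            p = 1.0 if diff == 0 else 0.0
        p_adj = 1.0 - (1.0 - p) ** n_pos
        rows.append(
            {
                "position": pos,
                "diff": diff,
                "t": t,
                "pvalue": p,
                "pvalue_sidak": min(p_adj, 1.0),
            }
        )
    return pd.DataFrame(rows)


def binomial_background_test(
    alt_count: int, coverage: int, background_rate: float
) -> float:
    """One-sided binomial p-value of a variant count against a background
    consensus error rate; single-sample companion to the replicate t-test."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    return float(sps.binom.sf(alt_count - 1, coverage, background_rate))


# ---------------------------------------------------------------------------
# error typing and profiles


@dataclass(frozen=True)
class ErrorTypeRates:
    """Non-reference event rates per class, as events / total coverage."""

    transition: float
    transversion: float
    deletion: float
    insertion: float
    ambiguous: float  # N calls
    overall: float  # all non-reference events / total coverage
    total_coverage: int

    def as_dict(self) -> dict[str, float]:
        return {
            "transition": self.transition,
            "transversion": self.transversion,
            "deletion": self.deletion,
            "insertion": self.insertion,
            "ambiguous": self.ambiguous,
            "overall": self.overall,
        }


def classify_errors(
    matrix: CountMatrix, exclusions: Iterable[int] = ()
) -> ErrorTypeRates:
    """Bin non-reference events into transitions (A<->G, C<->T),
    transversions, deletions and insertions over included positions.

    The four class rates (plus N calls) partition the overall non-reference
    rate computed on the same coverage denominator.
    """
    excl = set(int(p) for p in exclusions)
    include = np.array([i not in excl for i in range(len(matrix))], dtype=bool)
    counts = matrix.counts[include]
    ins = int(matrix.insertions[include].sum())
    refs = np.array([matrix.ref_seq[i] for i in range(len(matrix)) if include[i]])
    total_cov = int(counts.sum())
    ti = tv = 0
    for bi, base in enumerate(BASE_COLUMNS[:4]):
        obs = counts[:, bi]
        for ri, ref in enumerate(refs):
            if ref == base:
                continue
            n = int(obs[ri])
            if not n:
                continue
            if (ref, base) in TRANSITIONS:
                ti += n
            else:
                tv += n
    dels = int(counts[:, 5].sum())
    ns = int(counts[:, 4].sum())
    if total_cov == 0:
        nan = float("nan")
        return ErrorTypeRates(nan, nan, nan, nan, nan, nan, 0)
    return ErrorTypeRates(
        ti / total_cov,
        tv / total_cov,
        dels / total_cov,
        ins / total_cov,
        ns / total_cov,
        (ti + tv + dels + ins + ns) / total_cov,
        total_cov,
    )


def error_profile_correlation(
    rates_a: Sequence[float], rates_b: Sequence[float]
) -> TestResult:
    """Spearman rank correlation between two per-position error profiles.

    Constant profiles give an undefined rho, flagged as degenerate.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need >= 5 paired positions")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return TestResult(float("nan"), float("nan"), degenerate=True)
    rho, p = sps.spearmanr(a, b)
    return TestResult(float(rho), float(p))


# ---------------------------------------------------------------------------
# dilution series and plasma


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    saturated: bool
    predicted_top: float
    observed_top: float
    k_lowest: int


def dilution_linearity(
    loaded: Sequence[float], counts: Sequence[float], k_lowest: int = 4
) -> LinearityResult:
    """OLS on the ``k_lowest`` smallest input amounts; saturation is flagged
    when the highest amount under-yields its regression prediction."""
    loaded = np.asarray(loaded, dtype=float)
    counts = np.asarray(counts, dtype=float)
    amounts = np.unique(loaded)
    if amounts.size < k_lowest:
        raise ValueError(f"need >= {k_lowest} distinct input amounts")
    low = set(amounts[:k_lowest])
    mask = np.array([a in low for a in loaded])
    res = sps.linregress(loaded[mask], counts[mask])
    top = amounts[-1]
    observed_top = float(counts[loaded == top].mean())
    predicted_top = float(res.slope * top + res.intercept)
    return LinearityResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        saturated=observed_top < predicted_top,
        predicted_top=predicted_top,
        observed_top=observed_top,
        k_lowest=k_lowest,
    )


def molecules_per_ml_plasma(
    molecules: float,
    plasma_volume_ml: float,
    fraction_of_extract_used: float = 1.0,
    fraction_of_rt_used: float = 1.0,
) -> float:
    """Detected molecules per mL plasma, correcting for the fractions of the
    extract and of the RT reaction carried into the library."""
    if plasma_volume_ml <= 0:
        raise ValueError("plasma volume must be > 0")
    for f in (fraction_of_extract_used, fraction_of_rt_used):
        if not 0 < f <= 1:
            raise ValueError("fractions must be in (0, 1]")
    return molecules / (
        plasma_volume_ml * fraction_of_extract_used * fraction_of_rt_used
    )
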