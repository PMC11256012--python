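"""Evaluation statistics for 2D RP-RP fractionation.

Four statistics summarize how well an offline high-pH/low-pH
reversed-phase workflow performs, all computable from peptide evidence
tables (id, retention times, intensity, fractions of detection):

* **Peak capacity** — theoretical number of resolvable peaks.  For a
  gradient of length ``t_g`` and Gaussian peaks of baseline width
  ``w_b`` (= 4 sigma), the single-dimension capacity is
  ``Pc = 1 + t_g / w_b``; a 2D system with ``n`` fractions is upper
  bounded by ``n * Pc`` when the dimensions are fully orthogonal.
* **Fraction overlap** — the distribution of how many fractions each
  peptide is detected in; a high share of single-fraction peptides
  indicates sharp fractionation.
* **Signal recovery** — intensity of a fractionated-and-recombined
  sample relative to an unfractionated reference over the common
  peptides, the direct measure of sample loss.
* **Retention-time orthogonality** — correlation (ideally weak) between
  first- and second-dimension retention times, plus the occupancy of a
  rank-normalized RT grid.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeptideRecord",
    "PeakCapacityResult",
    "RecoveryResult",
    "OrthogonalityResult",
    "peak_capacity",
    "peak_capacity_2d",
    "overlap_histogram",
    "recovery_ratio",
    "rt_orthogonality",
    "read_peptide_tsv",
    "write_peptide_tsv",
]

logger = logging.getLogger(__name__)

# Gaussian width conversions: baseline = 4*sigma, fwhm = 2*sqrt(2*ln 2)*sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
BASE_PER_FWHM = 4.0 / FWHM_PER_SIGMA  # ~1.699


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide's evidence across a fractionation experiment.

    Retention times are optional because not every metric needs both
    dimensions; ``fractions`` is the set of fraction indices (1-based)
    in which the peptide was detected.
    """

    peptide_id: str
    rt_d1_s: float | None = None
    rt_d2_s: float | None = None
    intensity: float = 0.0
    fractions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        object.__setattr__(self, "fractions", frozenset(self.fractions))


@dataclass(frozen=True)
class PeakCapacityResult:
    t_gradient_s: float
    w_base_s: float
    pc_1d: float
    n_fractions: int = 1

    @property
    def pc_2d_upper(self) -> float:
        return self.n_fractions * self.pc_1d


@dataclass(frozen=True)
class RecoveryResult:
    n_common: int
    total_ratio: float
    median_ratio: float
    n_zero_reference: int = 0


@dataclass(frozen=True)
class OrthogonalityResult:
    pearson_r: float
    spearman_rho: float
    bin_occupancy: float
    n_bins: int
    n_pairs: int


def peak_capacity(
    t_gradient_s: float,
    peak_width_s: float,
    width_convention: str = "baseline",
    n_fractions: int = 1,
) -> PeakCapacityResult:
    """Theoretical 1D peak capacity ``1 + t_gradient / w_base``.

    ``width_convention`` says how ``peak_width_s`` was measured:
    ``"baseline"`` (4 sigma, used directly) or ``"fwhm"`` (converted via
    ``w_base = 4/2.355 * fwhm`` assuming Gaussian peaks).
    """
    if t_gradient_s <= 0 or peak_width_s <= 0:
        raise ValueError("gradient time and peak width must be positive")
    if width_convention == "baseline":
        w_base = peak_width_s
    elif width_convention == "fwhm":
        w_base = BASE_PER_FWHM * peak_width_s
    else:
        raise ValueError(f"unknown width convention {width_convention!r}")
    return PeakCapacityResult(
        t_gradient_s=t_gradient_s,
        w_base_s=w_base,
        pc_1d=1.0 + t_gradient_s / w_base,
        n_fractions=n_fractions,
    )


def peak_capacity_2d(pc_1d: float, n_fractions: int) -> float:
    """Upper-bound 2D peak capacity assuming fully orthogonal dimensions."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    return n_fractions * pc_1d


def overlap_histogram(
    records: Sequence[PeptideRecord],
) -> tuple[dict[int, int], float]:
    """Histogram of fractions-per-peptide and the single-fraction share.

    Returns ``({k: count}, percent_single)`` where ``k`` is the number of
    fractions a peptide was detected in and ``percent_single`` is
    ``100 * histogram[1] / total``.
    """
    if not records:
        raise ValueError("overlap_histogram needs at least one record")
    hist: dict[int, int] = {}
    for rec in records:
        k = len(rec.fractions)
        if k == 0:
            raise ValueError(f"peptide {rec.peptide_id} has no fractions")
        hist[k] = hist.get(k, 0) + 1
    percent_single = 100.0 * hist.get(1, 0) / len(records)
    return dict(sorted(hist.items())), percent_single


def recovery_ratio(
    test: Sequence[PeptideRecord], reference: Sequence[PeptideRecord]
) -> RecoveryResult:
    """Intensity recovery of ``test`` relative to ``reference``.

    Computed over peptide ids present in both tables.  ``total_ratio``
    is the ratio of summed intensities (the headline statistic for
    recovery experiments); ``median_ratio`` the median of per-peptide
    ratios.  Common peptides with zero reference intensity cannot form a
    ratio and are excluded with a logged count.
    """
    test_by_id = {r.peptide_id: r.intensity for r in test}
    ref_by_id = {r.peptide_id: r.intensity for r in reference}
    common = sorted(test_by_id.keys() & ref_by_id.keys())
    if not common:
        raise ValueError("no peptide ids common to both tables")
    usable = [p for p in common if ref_by_id[p] > 0]
    n_zero = len(common) - len(usable)
    if n_zero:
        logger.info("excluded %d common peptides with zero reference intensity", n_zero)
    if not usable:
        raise ValueError("all common peptides have zero reference intensity")
    t = np.array([test_by_id[p] for p in usable])
    r = np.array([ref_by_id[p] for p in usable])
    return RecoveryResult(
        n_common=len(usable),
        total_ratio=float(t.sum() / r.sum()),
        median_ratio=float(np.median(t / r)),
        n_zero_reference=n_zero,
    )


def rt_orthogonality(
    pairs: Iterable[tuple[float, float]] | np.ndarray, n_bins: int = 10
) -> OrthogonalityResult:
    """Correlation and grid occupancy of paired retention times.

    Pearson and Spearman are computed on the raw times; ``bin_occupancy``
    is the fraction of occupied cells in an ``n_bins x n_bins`` grid over
    rank-normalized times (so it measures how the joint distribution
    fills the separation space irrespective of the marginal gradients).
    Constant vectors leave the correlations undefined (NaN, flagged in a
    log message).
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (rt_d1, rt_d2) pairs")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    d1, d2 = arr[:, 0], arr[:, 1]
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        logger.warning("constant retention-time vector: correlation undefined")
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(d1, d2).statistic)
        spearman = float(stats.spearmanr(d1, d2).statistic)
    # rank-normalize to (0, 1] then bin
    u1 = stats.rankdata(d1, method="average") / len(d1)
    u2 = stats.rankdata(d2, method="average") / len(d2)
    grid, _, _ = np.histogram2d(u1, u2, bins=n_bins, range=[[0, 1], [0, 1]])
    occupancy = float(np.count_nonzero(grid) / grid.size)
    return OrthogonalityResult(
        pearson_r=pearson,
        spearman_rho=spearman,
        bin_occupancy=occupancy,
        n_bins=n_bins,
        n_pairs=arr.shape[0],
    )


# --- TSV interchange ---------------------------------------------------------

_COLUMNS = ["peptide_id", "rt_d1_s", "rt_d2_s", "intensity", "fractions"]


def write_peptide_tsv(records: Sequence[PeptideRecord], path) -> None:
    """Write records as TSV; ``fractions`` is semicolon-joined integers."""
    rows = []
    for r in records:
        rows.append(
            {
                "peptide_id": r.peptide_id,
                "rt_d1_s": r.rt_d1_s,
                "rt_d2_s": r.rt_d2_s,
                "intensity": r.intensity,
                "fractions": ";".join(str(f) for f in sorted(r.fractions)),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peptide_tsv(path) -> list[PeptideRecord]:
    """Read the TSV dialect written by :func:`write_peptide_tsv`.

    Blank retention times / intensities / fraction lists are allowed
    where a metric does not need them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "fractions": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        fractions = frozenset(
            int(tok)
            for tok in (row.fractions.split(";") if isinstance(row.fractions, str) else [])
            if tok
        )
        records.append(
            PeptideRecord(
                peptide_id=row.peptide_id,
                rt_d1_s=None if pd.isna(row.rt_d1_s) else float(row.rt_d1_s),
                rt_d2_s=None if pd.isna(row.rt_d2_s) else float(row.rt_d2_s),
                intensity=0.0 if pd.isna(row.intensity) else float(row.intensity),
                fractions=fractions,
            )
        )
    return records


def result_to_json(result) -> str:
    """Serialize any metric result dataclass as a JSON document."""
    d = asdict(result)
    if isinstance(result, PeakCapacityResult):
        d["pc_2d_upper"] = result.pc_2d_upper
    return json.dumps(d, indent=2)
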