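"""Protein quantification: pairwise-ratio geometric-median rollup.

A protein's case/control abundance ratio is computed in two stages:

1. per peptide, the geometric median of all cross-pair ratios
   ``a_i / b_j`` between its case and control observations;
2. per protein, the geometric median of those peptide ratios.

On positive scalars the geometric median is the multiplicative-scale median:
exponentiate the median of the logs.  For an even count the median of logs is
the midpoint of the two central values, i.e. the geometric mean of the two
central ratios.  This convention makes inversion symmetry exact:
swapping case and control inverts the ratio.

Reported ratios are saturated at a ceiling (default 100, floor 1/100), and a
protein reproducibly detected on one side only bypasses ratio estimation
entirely (presence/absence evaluation): it is reported at the ceiling
(case-only) or the floor (control-only) with ``capped=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Collection, Sequence

import numpy as np
import pandas as pd


class Presence(str, Enum):
    NO = "NO"
    CASE_ONLY = "CASE_ONLY"
    CONTROL_ONLY = "CONTROL_ONLY"


@dataclass(frozen=True)
class QuantConfig:
    """Saturation constants and the presence-call threshold.

    ``ratio_ceiling`` / ``p_floor`` are the conventions visible in published
    interactome tables (ratios print as at most 100, p-values as at least
    1e-17); ``min_present_replicates`` guards a presence-only call against
    single-replicate contamination.
    """

    ratio_ceiling: float = 100.0
    p_floor: float = 1e-17
    min_present_replicates: int = 3
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.ratio_ceiling <= 1:
            raise ValueError("ratio_ceiling must exceed 1")
        if not 0.0 < self.p_floor < 1.0:
            raise ValueError("p_floor must lie in (0, 1)")
        if self.min_present_replicates < 1:
            raise ValueError("min_present_replicates must be positive")

    @property
    def ratio_floor(self) -> float:
        return 1.0 / self.ratio_ceiling


@dataclass(frozen=True)
class ProteinRatio:
    """Rolled-up abundance ratio for one protein.

    ``ratio`` is NaN when the protein is not quantifiable (absent from both
    sides, or observed without any case/control peptide overlap and without
    meeting the presence-only rule).
    """

    accession: str
    ratio: float
    capped: bool
    n_peptides_used: int
    presence_only: Presence = Presence.NO

    @property
    def quantifiable(self) -> bool:
        return not math.isnan(self.ratio)


class PeptideAbsentError(ValueError):
    """A pairwise ratio was requested with an empty side."""


def _geometric_median(log_values: np.ndarray) -> float:
    # median of logs; numpy's even-count midpoint == log of geometric mean
    return float(np.exp(np.median(log_values)))


def pairwise_peptide_ratio(
    case_intensities: Sequence[float], control_intensities: Sequence[float]
) -> float:
    """Geometric median of all cross-pair ratios ``a_i / b_j``.

    Raises :class:`PeptideAbsentError` if either side is empty; the caller's
    presence/absence logic owns that case.
    """
    a = np.asarray(case_intensities, dtype=float)
    b = np.asarray(control_intensities, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PeptideAbsentError("peptide absent on one side")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("intensities must be strictly positive")
    log_ratios = np.subtract.outer(np.log(a), np.log(b)).ravel()
    return _geometric_median(log_ratios)


def _clamp(ratio: float, config: QuantConfig) -> tuple[float, bool]:
    if ratio > config.ratio_ceiling:
        return config.ratio_ceiling, True
    if ratio < config.ratio_floor:
        return config.ratio_floor, True
    return ratio, False


def protein_ratio(
    peptides: pd.DataFrame,
    case_samples: Collection[str],
    control_samples: Collection[str],
    config: QuantConfig = QuantConfig(),
    accession: str | None = None,
) -> ProteinRatio:
    """Roll one protein's peptide intensities up to a capped abundance ratio.

    ``peptides`` is the long-format table restricted to one accession (columns
    ``peptide_id, sample_id, intensity``; an ``accession`` column, if present,
    must be constant).  Only peptides observed in at least one case and one
    control sample contribute a pairwise ratio; the protein ratio is the
    geometric median of the peptide ratios, clamped to
    ``[1/ratio_ceiling, ratio_ceiling]``.

    Presence/absence: a protein detected (any peptide) in at least
    ``min_present_replicates`` case samples and in zero control samples is
    called ``CASE_ONLY`` at the ceiling; the mirror case is ``CONTROL_ONLY``
    at the floor.
    """
    case_samples = set(case_samples)
    control_samples = set(control_samples)
    if not case_samples or not control_samples:
        raise ValueError("case and control sample sets must be non-empty")
    if case_samples & control_samples:
        raise ValueError("case and control sample sets must be disjoint")
    if accession is None:
        if "accession" in peptides.columns and len(peptides):
            uniq = peptides["accession"].unique()
            if len(uniq) > 1:
                raise ValueError("protein_ratio expects a single-accession table")
            accession = str(uniq[0])
        else:
            accession = ""

    sub = peptides[peptides["sample_id"].isin(case_samples | control_samples)]
    in_case = sub["sample_id"].isin(case_samples)
    n_case_detected = sub.loc[in_case, "sample_id"].nunique()
    n_control_detected = sub.loc[~in_case, "sample_id"].nunique()

    if n_control_detected == 0 and n_case_detected >= config.min_present_replicates:
        return ProteinRatio(accession, config.ratio_ceiling, True, 0, Presence.CASE_ONLY)
    if n_case_detected == 0 and n_control_detected >= config.min_present_replicates:
        return ProteinRatio(accession, config.ratio_floor, True, 0, Presence.CONTROL_ONLY)

    log_peptide_ratios: list[float] = []
    for _, pep in sub.groupby("peptide_id", sort=True):
        a = pep.loc[pep["sample_id"].isin(case_samples), "intensity"].to_numpy(float)
        b = pep.loc[pep["sample_id"].isin(control_samples), "intensity"].to_numpy(float)
        if a.size and b.size:
            log_peptide_ratios.append(
                np.median(np.subtract.outer(np.log(a), np.log(b)).ravel())
            )
    if not log_peptide_ratios:
        return ProteinRatio(accession, math.nan, False, 0, Presence.NO)
    raw = float(np.exp(np.median(log_peptide_ratios)))
    ratio, capped = _clamp(raw, config)
    return ProteinRatio(accession, ratio, capped, len(log_peptide_ratios), Presence.NO)


def protein_ratios(
    peptides: pd.DataFrame,
    case_samples: Collection[str],
    control_samples: Collection[str],
    config: QuantConfig = QuantConfig(),
) -> pd.DataFrame:
    """Rolled-up ratios for every accession in a long peptide table at once.

    Same semantics as :func:`protein_ratio` applied per accession (the two
    are interchangeable; this one trades pandas bookkeeping for flat numpy
    passes).  Returns a DataFrame indexed by accession with columns
    ``ratio, capped, n_peptides_used, presence_only``.
    """
    case_samples = set(case_samples)
    control_samples = set(control_samples)
    if not case_samples or not control_samples:
        raise ValueError("case and control sample sets must be non-empty")
    if case_samples & control_samples:
        raise ValueError("case and control sample sets must be disjoint")

    sub = peptides[peptides["sample_id"].isin(case_samples | control_samples)]
    sub = sub.sort_values(["accession", "peptide_id"], kind="mergesort")
    is_case = sub["sample_id"].isin(case_samples).to_numpy()

    det_case = sub[is_case].groupby("accession")["sample_id"].nunique()
    det_ctrl = sub[~is_case].groupby("accession")["sample_id"].nunique()

    acc = sub["accession"].to_numpy()
    pep = sub["peptide_id"].to_numpy()
    logs = np.log(sub["intensity"].to_numpy(float))

    # segment boundaries where (accession, peptide) changes
    if len(sub):
        change = np.flatnonzero((acc[1:] != acc[:-1]) | (pep[1:] != pep[:-1])) + 1
        bounds = np.concatenate(([0], change, [len(sub)]))
    else:
        bounds = np.array([0])
    pep_logmed: dict[str, list[float]] = {}
    for lo, hi in zip(bounds, bounds[1:]):
        seg_case = logs[lo:hi][is_case[lo:hi]]
        seg_ctrl = logs[lo:hi][~is_case[lo:hi]]
        if seg_case.size and seg_ctrl.size:
            pep_logmed.setdefault(acc[lo], []).append(
                float(np.median(np.subtract.outer(seg_case, seg_ctrl).ravel()))
            )

    rows = []
    for accession in pd.unique(acc):
        n_case = int(det_case.get(accession, 0))
        n_ctrl = int(det_ctrl.get(accession, 0))
        if n_ctrl == 0 and n_case >= config.min_present_replicates:
            rows.append((accession, config.ratio_ceiling, True, 0, Presence.CASE_ONLY.value))
            continue
        if n_case == 0 and n_ctrl >= config.min_present_replicates:
            rows.append((accession, config.ratio_floor, True, 0, Presence.CONTROL_ONLY.value))
            continue
        meds = pep_logmed.get(accession)
        if not meds:
            rows.append((accession, math.nan, False, 0, Presence.NO.value))
            continue
        ratio, capped = _clamp(float(np.exp(np.median(meds))), config)
        rows.append((accession, ratio, capped, len(meds), Presence.NO.value))
    return pd.DataFrame(
        rows, columns=["accession", "ratio", "capped", "n_peptides_used", "presence_only"]
    ).set_index("accession")


def protein_abundance_per_sample(peptides: pd.DataFrame, sample: str) -> float:
    """Sum of the protein's peptide intensities in one sample; NaN if unseen."""
    vals = peptides.loc[peptides["sample_id"] == sample, "intensity"]
    if vals.empty:
        return math.nan
    return float(vals.sum())


def abundance_matrix(peptides: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Protein x sample matrix of log2 summed peptide intensities.

    Columns follow ``sample_ids``; cells with no observed peptide are NaN.
    This is the input the enrichment t-tests operate on.
    """
    sub = peptides[peptides["sample_id"].isin(set(sample_ids))]
    if sub.empty:
        return pd.DataFrame(columns=list(sample_ids))
    sums = sub.pivot_table(
        index="accession", columns="sample_id", values="intensity", aggfunc="sum"
    )
    mat = np.log2(sums.reindex(columns=list(sample_ids)))
    mat.index.name = "accession"
    return mat
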