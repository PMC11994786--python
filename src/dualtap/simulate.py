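"""Synthetic peptide-level AP-MS data with ground truth.

The generator emulates the statistical structure a dual-tag pull-down
analysis has to cope with, protein class by protein class:

``BEAD_BACKGROUND``
    sticks to the beads themselves; same mean intensity in all samples.
``TAG_CROSS_REACTIVE_HA`` / ``TAG_CROSS_REACTIVE_V5``
    binds the anti-tag antibody, not the bait: enriched in every sample of
    that arm regardless of genotype.  These are the proteins only the
    same-arm wild-type control can catch.
``CORE_COMPLEX``
    genuine bait partners pulled down through either tag: enriched in the
    case group of both contrasts.
``HA_SPECIFIC`` / ``V5_SPECIFIC``
    genuine partners seen only through one tag (cell-type-restricted
    interactions in the study this design models).
``ABSENT``
    listed in the truth table but never observed.

Peptide log2 intensities are normal around a class-and-group-dependent mean
(i.e. intensities are log-normal); missingness is censoring below a detection
floor plus a small uniform dropout.  A single :class:`numpy.random.Generator`
stream seeded from ``config.seed`` drives every draw, so identical
``(design, config)`` reproduce the table bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from dualtap.design import Arm, Genotype, Group, SampleRecord, StudyDesign, build_sample_records


class TruthClass(str, Enum):
    BEAD_BACKGROUND = "BEAD_BACKGROUND"
    TAG_CROSS_REACTIVE_HA = "TAG_CROSS_REACTIVE_HA"
    TAG_CROSS_REACTIVE_V5 = "TAG_CROSS_REACTIVE_V5"
    CORE_COMPLEX = "CORE_COMPLEX"
    HA_SPECIFIC = "HA_SPECIFIC"
    V5_SPECIFIC = "V5_SPECIFIC"
    ABSENT = "ABSENT"


#: accession prefix per truth class
_PREFIX = {
    TruthClass.BEAD_BACKGROUND: "BEAD",
    TruthClass.TAG_CROSS_REACTIVE_HA: "CRHA",
    TruthClass.TAG_CROSS_REACTIVE_V5: "CRV5",
    TruthClass.CORE_COMPLEX: "CORE",
    TruthClass.HA_SPECIFIC: "HASP",
    TruthClass.V5_SPECIFIC: "V5SP",
    TruthClass.ABSENT: "ABSN",
}

#: groups in which each class is enriched (by realized fold)
_ENRICHED_GROUPS: dict[TruthClass, tuple[Group, ...]] = {
    TruthClass.BEAD_BACKGROUND: (),
    TruthClass.TAG_CROSS_REACTIVE_HA: ((Genotype.TURNX, Arm.HA), (Genotype.WT, Arm.HA)),
    TruthClass.TAG_CROSS_REACTIVE_V5: ((Genotype.TURNX, Arm.V5), (Genotype.WT, Arm.V5)),
    TruthClass.CORE_COMPLEX: ((Genotype.TURNX, Arm.HA), (Genotype.TURNX, Arm.V5)),
    TruthClass.HA_SPECIFIC: ((Genotype.TURNX, Arm.HA),),
    TruthClass.V5_SPECIFIC: ((Genotype.TURNX, Arm.V5),),
    TruthClass.ABSENT: (),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults emulate the modelled study.

    Class counts default to 500 bead-background proteins, 30 cross-reactive
    binders per tag, an 11-member core complex, and 40 tag-specific partners
    per tag.  ``fold_enrichment`` (default 8) is the true case/control ratio
    of enriched classes, squarely inside the ~1.9-100 range the purge is
    expected to operate in; ``biological_cv`` is the coefficient of variation
    of a peptide's intensity across replicate pull-downs.
    """

    seed: int = 0
    n_background: int = 500
    n_cross_reactive_per_tag: int = 30
    n_core: int = 11
    n_ha_specific: int = 40
    n_v5_specific: int = 40
    n_absent: int = 0
    mean_peptides_per_protein: float = 4.0
    baseline_log2_intensity: float = 20.0
    protein_log2_sd: float = 1.5
    peptide_log2_sd: float = 1.0
    biological_cv: float = 0.25
    fold_enrichment: float = 8.0
    detection_floor_log2: float = 16.0
    stochastic_dropout: float = 0.05

    def __post_init__(self) -> None:
        counts = (
            self.n_background,
            self.n_cross_reactive_per_tag,
            self.n_core,
            self.n_ha_specific,
            self.n_v5_specific,
            self.n_absent,
        )
        if any(c < 0 for c in counts):
            raise ValueError("class counts must be nonnegative")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")
        if not 0.0 <= self.stochastic_dropout <= 1.0:
            raise ValueError("stochastic_dropout must lie in [0, 1]")
        if self.mean_peptides_per_protein < 1:
            raise ValueError("mean_peptides_per_protein must be >= 1")

    @property
    def class_counts(self) -> dict[TruthClass, int]:
        return {
            TruthClass.BEAD_BACKGROUND: self.n_background,
            TruthClass.TAG_CROSS_REACTIVE_HA: self.n_cross_reactive_per_tag,
            TruthClass.TAG_CROSS_REACTIVE_V5: self.n_cross_reactive_per_tag,
            TruthClass.CORE_COMPLEX: self.n_core,
            TruthClass.HA_SPECIFIC: self.n_ha_specific,
            TruthClass.V5_SPECIFIC: self.n_v5_specific,
            TruthClass.ABSENT: self.n_absent,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _log2_noise_sd(cv: float) -> float:
    # CV of a log-normal variable -> sd of its log2
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


def generate_dataset(
    design: StudyDesign,
    config: SimulationConfig,
    samples: Sequence[SampleRecord] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide intensity table and its ground truth.

    Returns
    -------
    peptides : pandas.DataFrame
        Long format with columns ``accession, peptide_id, sample_id,
        intensity`` (linear scale, strictly positive); censored or dropped
        observations are simply absent.
    truth : pandas.DataFrame
        Columns ``accession, truth_class, fold`` covering every accession,
        including those that never produced an observed peptide.
    """
    if samples is None:
        samples = build_sample_records(design)
    counts = config.class_counts
    n_proteins = sum(counts.values())
    if n_proteins == 0:
        raise ValueError("empty simulation: all class counts are zero")

    rng = np.random.default_rng(config.seed)
    sample_ids = np.array([s.sample_id for s in samples])
    groups = [s.group for s in samples]
    n_samples = len(samples)

    acc_list: list[str] = []
    cls_list: list[TruthClass] = []
    for cls in TruthClass:  # fixed class order => reproducible accession set
        for i in range(counts[cls]):
            acc_list.append(f"{_PREFIX[cls]}{i + 1:04d}")
            cls_list.append(cls)

    fold = np.array(
        [config.fold_enrichment if _ENRICHED_GROUPS[c] else 1.0 for c in cls_list]
    )
    truth = pd.DataFrame(
        {
            "accession": acc_list,
            "truth_class": [c.value for c in cls_list],
            "fold": fold,
        }
    )

    # per-protein peptide counts: 1 + Poisson(mean - 1)
    n_pep = 1 + rng.poisson(config.mean_peptides_per_protein - 1.0, size=n_proteins)
    base = config.baseline_log2_intensity + rng.normal(0.0, config.protein_log2_sd, n_proteins)

    log2_fold = np.log2(fold)
    enriched_mask = np.zeros((n_proteins, n_samples), dtype=bool)
    for p, cls in enumerate(cls_list):
        if cls is TruthClass.ABSENT:
            continue
        hot = set(_ENRICHED_GROUPS[cls])
        if hot:
            enriched_mask[p] = [g in hot for g in groups]

    noise_sd = _log2_noise_sd(config.biological_cv)
    frames: list[pd.DataFrame] = []
    for p, cls in enumerate(cls_list):
        if cls is TruthClass.ABSENT:
            continue
        k = int(n_pep[p])
        pep_offset = rng.normal(0.0, config.peptide_log2_sd, k)
        mean = (
            base[p]
            + pep_offset[:, None]
            + (enriched_mask[p] * log2_fold[p])[None, :]
        )  # (k, n_samples)
        vals = mean + rng.normal(0.0, noise_sd, size=mean.shape)
        keep = vals >= config.detection_floor_log2
        if config.stochastic_dropout > 0:
            keep &= rng.random(size=vals.shape) >= config.stochastic_dropout
        pi, si = np.nonzero(keep)
        if pi.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "accession": acc_list[p],
                    "peptide_id": np.char.add(f"{acc_list[p]}_pep", (pi + 1).astype(str)),
                    "sample_id": sample_ids[si],
                    "intensity": np.exp2(vals[pi, si]),
                }
            )
        )
    if frames:
        peptides = pd.concat(frames, ignore_index=True)
    else:
        peptides = pd.DataFrame(columns=["accession", "peptide_id", "sample_id", "intensity"])
    return peptides, truth


def truth_positive_set(truth: pd.DataFrame, tag: Arm | str) -> set[str]:
    """Accessions the purge should recover for ``tag``: core + tag-specific.

    Cross-reactive and bead-background proteins are never members.
    """
    tag = tag if isinstance(tag, Arm) else Arm(str(tag).upper())
    if tag not in (Arm.HA, Arm.V5):
        raise ValueError("tag must be HA or V5")
    wanted = {
        TruthClass.CORE_COMPLEX.value,
        (TruthClass.HA_SPECIFIC if tag is Arm.HA else TruthClass.V5_SPECIFIC).value,
    }
    if truth.empty:
        return set()
    return set(truth.loc[truth["truth_class"].isin(wanted), "accession"])


def write_peptide_table(peptides: pd.DataFrame, path: str | Path) -> None:
    """TSV with columns accession, peptide_id, sample_id, intensity."""
    peptides.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "peptide_id": str, "sample_id": str})
    missing = {"accession", "peptide_id", "sample_id", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"peptide table is missing columns: {sorted(missing)}")
    df = df.dropna(subset=["intensity"])
    if (df["intensity"] <= 0).any():
        raise ValueError("peptide intensities must be strictly positive")
    return df.reset_index(drop=True)


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"accession": str, "truth_class": str})
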