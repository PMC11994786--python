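"""The three-negative-control significance purge, as a model/results pair.

For a tag's contrast, every protein detected in the case group
``(TURNX, tag)`` is scored two ways:

* an abundance ratio against the three control groups **pooled**
  (:mod:`dualtap.quantify`), because an interactome table prints one ratio
  column per protein;
* a two-sided Welch t-test on log2 abundances against **each** control group
  separately, because the purge demands significance against all three.

A protein is retained iff ``max`` of the three p-values is at or below
``alpha`` and its ratio is at least ``min_fold``.  The reported p-value is
that maximum — the weakest of the three comparisons.  No multiple-testing
correction enters the decision (the modelled procedure uses raw p <= 0.05); a
Benjamini-Hochberg column is emitted for information only.

:class:`InteractionScreen` is the model (data + contrast + configuration);
:meth:`InteractionScreen.fit` returns :class:`InteractionScreenResults`
carrying the per-protein table, the purged :class:`Interactome`, a
``summary()`` and a volcano plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from dualtap.design import (
    Arm,
    ContrastSpec,
    Group,
    SampleRecord,
    default_contrasts,
    load_sample_sheet,
    samples_in_group,
)
from dualtap.quantify import Presence, QuantConfig, abundance_matrix, protein_ratios
from dualtap.simulate import read_peptide_table


class ReplicateUnit(str, Enum):
    """What counts as one observation in the t-tests.

    ``MOUSE_MEAN`` (default) averages the fractions of each mouse on the log2
    scale into a single value — the fractions of one animal are not
    independent; ``FRACTION`` treats every IP fraction as one observation.
    """

    MOUSE_MEAN = "MOUSE_MEAN"
    FRACTION = "FRACTION"


@dataclass(frozen=True)
class PurgeConfig:
    alpha: float = 0.05
    min_fold: float = 1.0
    replicate_unit: ReplicateUnit = ReplicateUnit.MOUSE_MEAN
    p_floor: float = 1e-17

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1 (enrichment direction)")


class GroupEmptyError(ValueError):
    """A contrast group has no samples in the sheet."""


def group_abundances(
    peptides: pd.DataFrame,
    samples: Sequence[SampleRecord],
    group: Group,
    unit: ReplicateUnit = ReplicateUnit.MOUSE_MEAN,
) -> pd.DataFrame:
    """Protein x replicate-unit matrix of log2 abundances for one group.

    With ``MOUSE_MEAN`` the columns are mice and each cell is the log2-scale
    mean over that mouse's fractions (missing fractions ignored; a mouse with
    no observation at all contributes NaN).  With ``FRACTION`` the columns are
    the individual fractions.
    """
    members = samples_in_group(samples, group)
    if not members:
        raise GroupEmptyError(f"no samples in group {group!r}")
    mat = abundance_matrix(peptides, [s.sample_id for s in members])
    if ReplicateUnit(unit) is ReplicateUnit.FRACTION:
        return mat
    by_mouse: dict[str, list[str]] = {}
    for s in members:
        by_mouse.setdefault(s.mouse_id, []).append(s.sample_id)
    cols = {}
    for mouse in sorted(by_mouse):
        cols[mouse] = mat[by_mouse[mouse]].mean(axis=1, skipna=True)
    return pd.DataFrame(cols, index=mat.index)


def welch_p(
    case_values: Sequence[float],
    control_values: Sequence[float],
    p_floor: float = 1e-17,
    min_present: int = 3,
) -> float:
    """Two-sided Welch t-test p-value on log2 abundances, floored at ``p_floor``.

    Degenerate rules, applied before the t statistic:

    * both groups constant and equal -> 1.0;
    * both groups constant and different -> ``p_floor``;
    * one side has at least ``min_present`` values and the other none ->
      ``p_floor`` (presence-only convention);
    * otherwise fewer than 2 values in either group -> NaN, the
      "insufficient replication" marker (protein excluded from testing).
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if b.size == 0 and a.size >= min_present:
        return p_floor
    if a.size == 0 and b.size >= min_present:
        return p_floor
    if a.size < 2 or b.size < 2:
        return math.nan
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 1.0 if a[0] == b[0] else p_floor
    # closed-form Welch statistic with Satterthwaite degrees of freedom
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return min(max(p, p_floor), 1.0)


# column order of the per-protein table and its TSV twin
_TSV_COLUMNS = {
    "accession": "Accession",
    "description": "Description",
    "ratio": "Abundance_ratio",
    "capped": "Ratio_capped",
    "p_vs_ctrl1": "p_vs_ctrl1",
    "p_vs_ctrl2": "p_vs_ctrl2",
    "p_vs_ctrl3": "p_vs_ctrl3",
    "p_reported": "p_reported",
    "q_bh": "q_BH",
    "presence_only": "Presence_only",
    "annotation": "Annotation",
}


@dataclass
class Interactome:
    """The purged significant-protein list for one tag."""

    tag: Arm
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def accessions(self) -> set[str]:
        return set(self.records["accession"])

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        out = self.records[list(_TSV_COLUMNS)].rename(columns=_TSV_COLUMNS)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, tag: Arm | str) -> "Interactome":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"Accession": str})
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed interactome TSV {path}: {exc}") from exc
        missing = set(_TSV_COLUMNS.values()) - set(df.columns)
        if missing:
            raise ValueError(
                f"interactome TSV {path} is missing columns: {sorted(missing)}"
            )
        inv = {v: k for k, v in _TSV_COLUMNS.items()}
        tag = tag if isinstance(tag, Arm) else Arm(str(tag).upper())
        return cls(tag=tag, records=df.rename(columns=inv))


class InteractionScreen:
    """Model: one tag's case group against its three negative controls.

    Parameters
    ----------
    peptides : pandas.DataFrame
        Long-format peptide intensities (accession, peptide_id, sample_id,
        intensity).
    samples : sequence of SampleRecord
        The sample sheet.
    contrast : ContrastSpec
        Case group and the three control groups; see
        :func:`dualtap.design.default_contrasts`.
    quant_config, purge_config : optional
        Saturation/presence and significance settings.
    annotations, descriptions : optional mappings
        accession -> category / free-text description, carried into the
        output table.
    """

    def __init__(
        self,
        peptides: pd.DataFrame,
        samples: Sequence[SampleRecord],
        contrast: ContrastSpec,
        quant_config: QuantConfig | None = None,
        purge_config: PurgeConfig | None = None,
        annotations: Mapping[str, str] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.peptides = peptides
        self.samples = list(samples)
        self.contrast = contrast
        self.quant_config = quant_config or QuantConfig()
        self.purge_config = purge_config or PurgeConfig()
        self.annotations = dict(annotations or {})
        self.descriptions = dict(descriptions or {})
        for group in (contrast.case_group, *contrast.control_groups):
            if not samples_in_group(self.samples, group):
                raise GroupEmptyError(f"no samples in contrast group {group!r}")

    @classmethod
    def from_files(
        cls,
        peptide_path: str | Path,
        sample_sheet_path: str | Path,
        tag: Arm | str,
        **kwargs,
    ) -> "InteractionScreen":
        tag = tag if isinstance(tag, Arm) else Arm(str(tag).upper())
        contrast = next(c for c in default_contrasts() if c.tag is tag)
        return cls(
            read_peptide_table(peptide_path),
            load_sample_sheet(sample_sheet_path),
            contrast,
            **kwargs,
        )

    def fit(self) -> "InteractionScreenResults":
        qc, pc = self.quant_config, self.purge_config
        case_ids = [s.sample_id for s in samples_in_group(self.samples, self.contrast.case_group)]
        pooled_ctrl_ids: list[str] = []
        for g in self.contrast.control_groups:
            pooled_ctrl_ids += [s.sample_id for s in samples_in_group(self.samples, g)]

        detected = set(
            self.peptides.loc[self.peptides["sample_id"].isin(case_ids), "accession"]
        )
        n_detected = len(detected)

        case_units = group_abundances(
            self.peptides, self.samples, self.contrast.case_group, pc.replicate_unit
        )
        ctrl_units = [
            group_abundances(self.peptides, self.samples, g, pc.replicate_unit)
            for g in self.contrast.control_groups
        ]

        accs = sorted(detected)
        ratios = protein_ratios(self.peptides, case_ids, pooled_ctrl_ids, qc).reindex(accs)
        case_mat = case_units.reindex(accs).to_numpy(float)
        ctrl_mats = [cu.reindex(accs).to_numpy(float) for cu in ctrl_units]

        rows = []
        n_insufficient = 0
        for i, acc in enumerate(accs):
            ps = [
                welch_p(case_mat[i], cm[i], pc.p_floor, qc.min_present_replicates)
                for cm in ctrl_mats
            ]
            if any(math.isnan(p) for p in ps):
                n_insufficient += 1
                continue
            p_reported = max(ps)
            ratio = float(ratios["ratio"].iloc[i])
            rows.append(
                {
                    "accession": acc,
                    "description": self.descriptions.get(acc, ""),
                    "ratio": ratio,
                    "capped": bool(ratios["capped"].iloc[i]),
                    "presence_only": ratios["presence_only"].iloc[i],
                    "p_vs_ctrl1": ps[0],
                    "p_vs_ctrl2": ps[1],
                    "p_vs_ctrl3": ps[2],
                    "p_reported": p_reported,
                    "annotation": self.annotations.get(acc, ""),
                    "significant": (
                        not math.isnan(ratio)
                        and p_reported <= pc.alpha
                        and ratio >= pc.min_fold
                    ),
                }
            )
        records = pd.DataFrame(
            rows,
            columns=[
                "accession",
                "description",
                "ratio",
                "capped",
                "presence_only",
                "p_vs_ctrl1",
                "p_vs_ctrl2",
                "p_vs_ctrl3",
                "p_reported",
                "annotation",
                "significant",
            ],
        )
        if len(records):
            records["q_bh"] = multipletests(records["p_reported"], method="fdr_bh")[1]
            records = records.sort_values(
                ["ratio", "p_reported", "accession"],
                ascending=[False, True, True],
                na_position="last",
                kind="mergesort",
            ).reset_index(drop=True)
        else:
            records["q_bh"] = pd.Series(dtype=float)
        return InteractionScreenResults(
            model=self,
            records=records,
            n_detected=n_detected,
            n_insufficient=n_insufficient,
        )


class InteractionScreenResults:
    """Per-protein ratios, three control p-values, and the purged interactome."""

    def __init__(
        self,
        model: InteractionScreen,
        records: pd.DataFrame,
        n_detected: int,
        n_insufficient: int,
    ) -> None:
        self.model = model
        self.records = records
        self.n_detected = n_detected
        self.n_insufficient = n_insufficient

    @property
    def n_tested(self) -> int:
        return len(self.records)

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum()) if len(self.records) else 0

    @property
    def interactome(self) -> Interactome:
        sig = self.records[self.records["significant"]].reset_index(drop=True)
        return Interactome(
            tag=self.model.contrast.tag, records=sig, provenance=self.provenance()
        )

    def provenance(self) -> dict:
        c = self.model.contrast
        return {
            "tag": c.tag.value,
            "case_group": [g.value for g in c.case_group],
            "control_groups": [[a.value, b.value] for a, b in c.control_groups],
            "quant_config": asdict(self.model.quant_config),
            "purge_config": {
                **asdict(self.model.purge_config),
                "replicate_unit": self.model.purge_config.replicate_unit.value,
            },
            "n_detected": self.n_detected,
            "n_tested": self.n_tested,
            "n_excluded_insufficient_replication": self.n_insufficient,
            "n_significant": self.n_significant,
        }

    def summary(self, top: int = 10) -> str:
        c = self.model.contrast
        pc = self.model.purge_config
        lines = [
            f"Interaction screen: tag {c.tag.value}",
            f"  case group        : {c.case_group[0].value}/{c.case_group[1].value}",
            "  control groups    : "
            + ", ".join(f"{g[0].value}/{g[1].value}" for g in c.control_groups),
            f"  replicate unit    : {pc.replicate_unit.value}",
            f"  alpha / min fold  : {pc.alpha} / {pc.min_fold}",
            f"  detected in case  : {self.n_detected}",
            f"  tested            : {self.n_tested}"
            f"  (excluded, insufficient replication: {self.n_insufficient})",
            f"  significant       : {self.n_significant}",
            "",
        ]
        if len(self.records):
            head = self.records[self.records["significant"]].head(top)
            lines.append(
                head[["accession", "ratio", "p_reported", "presence_only"]].to_string(
                    index=False, float_format=lambda v: f"{v:.4g}"
                )
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path, significant_only: bool = False) -> None:
        df = self.records[self.records["significant"]] if significant_only else self.records
        out = df[list(_TSV_COLUMNS)].rename(columns=_TSV_COLUMNS)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot_volcano(self, ax=None):
        """log2 ratio vs -log10 reported p; significant proteins highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        df = self.records.dropna(subset=["ratio"])
        x = np.log2(df["ratio"])
        y = -np.log10(df["p_reported"])
        sig = df["significant"].to_numpy(bool)
        ax.scatter(x[~sig], y[~sig], s=8, c="0.7", label="purged")
        ax.scatter(x[sig], y[sig], s=8, c="crimson", label="retained")
        ax.axhline(-math.log10(self.model.purge_config.alpha), ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 abundance ratio (case / pooled controls)")
        ax.set_ylabel("-log10 max p over 3 controls")
        ax.set_title(f"{self.model.contrast.tag.value} screen")
        ax.legend(frameon=False, fontsize=8)
        return ax


def run_purge(
    peptides: pd.DataFrame,
    samples: Sequence[SampleRecord],
    contrast: ContrastSpec,
    quant_config: QuantConfig | None = None,
    purge_config: PurgeConfig | None = None,
    **kwargs,
) -> Interactome:
    """Fit the screen for one contrast and return its purged interactome."""
    return (
        InteractionScreen(peptides, samples, contrast, quant_config, purge_config, **kwargs)
        .fit()
        .interactome
    )
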