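import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualtap.design import (
    Arm,
    Genotype,
    StudyDesign,
    build_sample_records,
    default_contrasts,
)
from dualtap.enrich import (
    GroupEmptyError,
    InteractionScreen,
    Interactome,
    PurgeConfig,
    ReplicateUnit,
    group_abundances,
    run_purge,
    welch_p,
)
from dualtap.quantify import QuantConfig
from dualtap.simulate import SimulationConfig, generate_dataset


# ---------------------------------------------------------------- group_abundances

def _one_protein_table(values_by_sample):
    return pd.DataFrame(
        [("P1", "pep1", s, v) for s, v in values_by_sample.items()],
        columns=["accession", "peptide_id", "sample_id", "intensity"],
    )


def test_mouse_mean_averages_fractions_on_log2_scale(samples):
    mouse = samples[0].mouse_id
    ids = [s.sample_id for s in samples if s.mouse_id == mouse and s.arm is Arm.HA]
    tbl = _one_protein_table(
        {ids[0]: 2.0**10, ids[1]: 2.0**10, ids[2]: 2.0**12, ids[3]: 2.0**12}
    )
    out = group_abundances(tbl, samples, (Genotype.WT, Arm.HA), ReplicateUnit.MOUSE_MEAN)
    assert out.loc["P1", mouse] == pytest.approx(11.0)
    # mice with no observation contribute missing
    assert out.loc["P1"].notna().sum() == 1
    assert out.shape[1] == 4  # one column per mouse in the group


def test_fraction_unit_keeps_every_fraction(samples, default_dataset):
    peptides, _ = default_dataset
    out = group_abundances(peptides, samples, (Genotype.TURNX, Arm.HA), ReplicateUnit.FRACTION)
    assert out.shape[1] == 16  # 4 mice x 4 fractions


def test_empty_group_is_named(samples, default_dataset):
    peptides, _ = default_dataset
    ha_only = [s for s in samples if s.arm is Arm.HA]
    with pytest.raises(GroupEmptyError, match="IG"):
        group_abundances(peptides, ha_only, (Genotype.WT, Arm.IG))


# ---------------------------------------------------------------------- welch_p

def test_welch_matches_t_distribution_oracle():
    case = [5.0, 5.2, 4.8, 5.1]
    ctrl = [3.0, 3.1, 2.9, 3.0]
    # independent oracle: scipy's Welch implementation
    expected = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    assert welch_p(case, ctrl) == pytest.approx(expected, rel=1e-10)

    rng = np.random.default_rng(42)
    for _ in range(300):
        a = rng.normal(0, 1, rng.integers(2, 9))
        b = rng.normal(rng.normal(), rng.uniform(0.5, 3), rng.integers(2, 9))
        expected = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        assert welch_p(a, b) == pytest.approx(expected, rel=1e-10)


def test_welch_degenerate_rules():
    assert welch_p([5, 5, 5, 5], [5, 5, 5, 5]) == 1.0
    assert welch_p([5, 5, 5, 5], [3, 3, 3, 3]) == 1e-17
    # presence-only convention: case in >= 3 replicates, control absent
    assert welch_p([5.0, 5.1, 4.9, 5.0], []) == 1e-17
    assert welch_p([], [5.0, 5.1, 4.9]) == 1e-17
    # insufficient replication outside the degenerate rules
    assert math.isnan(welch_p([5.0], [3.0, 3.1]))
    assert math.isnan(welch_p([5.0, 5.1], [3.0]))
    assert math.isnan(welch_p([5.0, 5.1], []))  # 2 < min_present
    # NaNs are treated as missing
    assert welch_p([5, 5.1, np.nan, 4.9, 5.0], [3, 3.1, 2.9, np.nan]) == pytest.approx(
        welch_p([5, 5.1, 4.9, 5.0], [3, 3.1, 2.9])
    )


def test_welch_p_is_floored():
    a = np.array([50.0, 50.1, 49.9, 50.0])
    b = np.array([1.0, 1.1, 0.9, 1.0])
    raw = welch_p(a, b)
    assert raw < 1e-3
    assert welch_p(a, b, p_floor=1e-3) == 1e-3


# -------------------------------------------------------------------- the purge

def _crafted_dataset(design, match_groups=(), depleted=False):
    """One protein; case group enriched 8x over every group not in match_groups.

    Groups in ``match_groups`` get the same constant abundance as the case
    group, so their Welch comparison is the degenerate equal-constant p=1.
    """
    samples = build_sample_records(design)
    case_group = (Genotype.TURNX, Arm.HA)
    rows = []
    for s in samples:
        if s.group == case_group or s.group in match_groups:
            val = 32.0 if not depleted else 4.0
        else:
            val = 4.0 if not depleted else 32.0
        rows.append(("P1", "pep1", s.sample_id, val))
    return samples, pd.DataFrame(
        rows, columns=["accession", "peptide_id", "sample_id", "intensity"]
    )


@pytest.mark.parametrize("match_idx", [None, 0, 1, 2])
def test_significance_requires_all_three_controls(match_idx):
    """A single non-significant control comparison excludes the protein."""
    design = StudyDesign()
    contrast = default_contrasts()[0]
    match = () if match_idx is None else (contrast.control_groups[match_idx],)
    samples, peptides = _crafted_dataset(design, match_groups=match)
    interactome = run_purge(peptides, samples, contrast)
    if match_idx is None:
        assert interactome.accessions == {"P1"}
    else:
        assert interactome.accessions == set()


def test_cross_reactive_pattern_is_excluded_by_same_arm_control():
    """Enriched on HA beads in both genotypes: passes both Ig comparisons but
    fails the (WT, HA) one, the reason that control exists."""
    design = StudyDesign()
    contrast = default_contrasts()[0]
    samples, peptides = _crafted_dataset(design, match_groups=((Genotype.WT, Arm.HA),))
    res = InteractionScreen(peptides, samples, contrast).fit()
    row = res.records.iloc[0]
    assert row["p_vs_ctrl1"] > 0.05  # same-arm WT control
    assert row["p_vs_ctrl2"] <= 0.05 and row["p_vs_ctrl3"] <= 0.05
    assert not row["significant"]


def test_depleted_protein_excluded_by_direction_rule():
    design = StudyDesign()
    contrast = default_contrasts()[0]
    samples, peptides = _crafted_dataset(design, depleted=True)
    res = InteractionScreen(peptides, samples, contrast).fit()
    row = res.records.iloc[0]
    assert row["ratio"] < 1.0
    assert row["p_reported"] <= 0.001
    assert not row["significant"]


def test_purge_monotonic_in_alpha_and_min_fold(small_dataset):
    samples, peptides, _ = small_dataset
    contrast = default_contrasts()[0]
    sizes_alpha = []
    for alpha in (0.001, 0.01, 0.05, 0.2):
        it = run_purge(peptides, samples, contrast, purge_config=PurgeConfig(alpha=alpha))
        sizes_alpha.append(len(it))
    assert sizes_alpha == sorted(sizes_alpha)
    sizes_fold = []
    for mf in (1.0, 2.0, 4.0, 16.0):
        it = run_purge(peptides, samples, contrast, purge_config=PurgeConfig(min_fold=mf))
        sizes_fold.append(len(it))
    assert sizes_fold == sorted(sizes_fold)[::-1]


def test_purge_output_subset_and_fixed_point(small_dataset):
    samples, peptides, _ = small_dataset
    contrast = default_contrasts()[0]
    first = run_purge(peptides, samples, contrast)
    detected = set(peptides["accession"])
    assert first.accessions <= detected
    restricted = peptides[peptides["accession"].isin(first.accessions)]
    second = run_purge(restricted, samples, contrast)
    assert second.accessions == first.accessions


def test_purge_deterministic_output(tmp_path, small_dataset):
    samples, peptides, _ = small_dataset
    contrast = default_contrasts()[1]
    paths = []
    for i in (1, 2):
        res = InteractionScreen(peptides, samples, contrast).fit()
        p = tmp_path / f"run{i}.tsv"
        res.to_tsv(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_records_sorted_by_ratio_then_p(small_dataset):
    samples, peptides, _ = small_dataset
    res = InteractionScreen(peptides, samples, default_contrasts()[0]).fit()
    df = res.records.dropna(subset=["ratio"])
    key = list(zip(-df["ratio"], df["p_reported"], df["accession"]))
    assert key == sorted(key)


def test_results_summary_and_interactome_roundtrip(tmp_path, small_dataset):
    samples, peptides, _ = small_dataset
    res = InteractionScreen(peptides, samples, default_contrasts()[0]).fit()
    text = res.summary()
    assert "tag HA" in text and str(res.n_significant) in text
    it = res.interactome
    path = tmp_path / "ha.tsv"
    it.to_tsv(path)
    back = Interactome.from_tsv(path, "HA")
    assert back.accessions == it.accessions
    assert back.tag is Arm.HA


def test_missing_contrast_group_raises(small_dataset):
    samples, peptides, _ = small_dataset
    no_ig = [s for s in samples if s.arm is not Arm.IG]
    with pytest.raises(GroupEmptyError):
        InteractionScreen(peptides, no_ig, default_contrasts()[0])


def test_purge_config_validation():
    with pytest.raises(ValueError):
        PurgeConfig(alpha=0.0)
    with pytest.raises(ValueError):
        PurgeConfig(min_fold=0.5)
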