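import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualtap.quantify import (
    PeptideAbsentError,
    Presence,
    QuantConfig,
    pairwise_peptide_ratio,
    protein_abundance_per_sample,
    protein_ratio,
    protein_ratios,
)


def brute_force_rollup(table: dict[str, tuple[list[float], list[float]]]) -> float:
    """Independent oracle: explicit cross-pair enumeration + sort-based median.

    ``table`` maps peptide id -> (case intensities, control intensities).
    """

    def sorted_median(vals):
        vals = sorted(vals)
        n = len(vals)
        return vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])

    pep_medians = []
    for case, ctrl in table.values():
        if case and ctrl:
            pep_medians.append(
                sorted_median([math.log(a) - math.log(b) for a in case for b in ctrl])
            )
    return math.exp(sorted_median(pep_medians))


def _table(peptide_obs: dict[str, tuple[list[float], list[float]]]) -> pd.DataFrame:
    rows = []
    for pid, (case, ctrl) in peptide_obs.items():
        for i, v in enumerate(case):
            rows.append(("P1", pid, f"case{i}", v))
        for i, v in enumerate(ctrl):
            rows.append(("P1", pid, f"ctrl{i}", v))
    return pd.DataFrame(rows, columns=["accession", "peptide_id", "sample_id", "intensity"])


CASE4 = [f"case{i}" for i in range(4)]
CTRL4 = [f"ctrl{i}" for i in range(4)]


@pytest.mark.parametrize(
    "case, ctrl, expected",
    [
        ([8, 8], [2, 2], 4.0),  # all four cross-ratios equal 4
        ([4], [1, 16], 1.0),  # ratios {4, 1/4}: geometric mean of central pair
        ([6, 12, 24], [3], 4.0),  # ratios {2, 4, 8}: odd-count median
    ],
)
def test_pairwise_ratio_examples(case, ctrl, expected):
    assert pairwise_peptide_ratio(case, ctrl) == pytest.approx(expected, rel=1e-12)


def test_pairwise_ratio_empty_side_signals_absence():
    with pytest.raises(PeptideAbsentError):
        pairwise_peptide_ratio([], [1.0])
    with pytest.raises(PeptideAbsentError):
        pairwise_peptide_ratio([1.0], [])


def test_protein_ratio_odd_count_median():
    tbl = _table({"p1": ([2], [1]), "p2": ([4], [1]), "p3": ([8], [1])})
    pr = protein_ratio(tbl, ["case0"], ["ctrl0"])
    assert pr.ratio == pytest.approx(4.0)
    assert not pr.capped
    assert pr.n_peptides_used == 3
    assert pr.presence_only is Presence.NO


def test_protein_ratio_ceiling_cap():
    tbl = _table({"p1": ([300], [1]), "p2": ([900], [1])})
    pr = protein_ratio(tbl, ["case0"], ["ctrl0"])
    assert pr.ratio == 100.0
    assert pr.capped


def test_presence_only_case():
    # seen in 4/4 case samples, zero control samples -> ceiling, CASE_ONLY
    tbl = _table({"p1": ([10, 11, 9, 10], [])})
    pr = protein_ratio(tbl, CASE4, CTRL4)
    assert pr.presence_only is Presence.CASE_ONLY
    assert pr.ratio == 100.0 and pr.capped
    # mirror: control-only at the floor
    tbl2 = _table({"p1": ([], [10, 11, 9, 10])})
    pr2 = protein_ratio(tbl2, CASE4, CTRL4)
    assert pr2.presence_only is Presence.CONTROL_ONLY
    assert pr2.ratio == pytest.approx(0.01)


def test_presence_call_needs_min_replicates():
    # 2 of 4 case samples < min_present_replicates=3 -> not quantifiable
    tbl = _table({"p1": ([10, 11], [])})
    pr = protein_ratio(tbl, CASE4, CTRL4)
    assert pr.presence_only is Presence.NO
    assert not pr.quantifiable and pr.n_peptides_used == 0


def test_absent_protein_not_quantifiable():
    tbl = _table({"p1": ([1.0], [1.0])})
    pr = protein_ratio(tbl, ["caseX"], ["ctrlX"])
    assert not pr.quantifiable


positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False, allow_infinity=False)


@st.composite
def peptide_tables(draw):
    n_pep = draw(st.integers(1, 5))
    table = {}
    any_pair = False
    for i in range(n_pep):
        case = draw(st.lists(positive, min_size=0, max_size=4))
        ctrl = draw(st.lists(positive, min_size=0, max_size=4))
        table[f"p{i}"] = (case, ctrl)
        any_pair = any_pair or (bool(case) and bool(ctrl))
    if not any_pair:
        table["p0"] = ([draw(positive)], [draw(positive)])
    return table


@settings(max_examples=200, deadline=None, derandomize=True)
@given(peptide_tables())
def test_rollup_matches_brute_force_oracle(table):
    df = _table(table)
    pr = protein_ratio(df, CASE4, CTRL4, QuantConfig(ratio_ceiling=1e30))
    assert pr.ratio == pytest.approx(brute_force_rollup(table), rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(peptide_tables())
def test_inversion_symmetry_and_scale_equivariance(table):
    # ensure both sides observed for every peptide, so no presence-only path
    table = {k: (c or [1.0], t or [1.0]) for k, (c, t) in table.items()}
    df = _table(table)
    cfg = QuantConfig(ratio_ceiling=1e30)
    fwd = protein_ratio(df, CASE4, CTRL4, cfg).ratio
    rev = protein_ratio(df, CTRL4, CASE4, cfg).ratio
    assert fwd * rev == pytest.approx(1.0, rel=1e-9)
    scaled = df.copy()
    case_mask = scaled["sample_id"].str.startswith("case")
    scaled.loc[case_mask, "intensity"] *= 7.5
    assert protein_ratio(scaled, CASE4, CTRL4, cfg).ratio == pytest.approx(
        7.5 * fwd, rel=1e-9
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(peptide_tables())
def test_clamp_idempotent_and_bounded(table):
    df = _table(table)
    cfg = QuantConfig()
    pr = protein_ratio(df, CASE4, CTRL4, cfg)
    assert cfg.ratio_floor <= pr.ratio <= cfg.ratio_ceiling
    # capping an already-capped value changes nothing: rerun on same input
    again = protein_ratio(df, CASE4, CTRL4, cfg)
    assert again.ratio == pr.ratio and again.capped == pr.capped


def test_bulk_rollup_matches_scalar(small_dataset):
    samples, peptides, _ = small_dataset
    case = [s.sample_id for s in samples if s.group[0].value == "TURNX" and s.group[1].value == "HA"]
    ctrl = [s.sample_id for s in samples if s.group[1].value == "IG"]
    bulk = protein_ratios(peptides, case, ctrl)
    rng = np.random.default_rng(0)
    for acc in rng.choice(bulk.index.to_numpy(), size=25, replace=False):
        scalar = protein_ratio(
            peptides[peptides["accession"] == acc], case, ctrl, accession=acc
        )
        row = bulk.loc[acc]
        if math.isnan(scalar.ratio):
            assert math.isnan(row["ratio"])
        else:
            assert row["ratio"] == pytest.approx(scalar.ratio, rel=1e-12)
        assert row["presence_only"] == scalar.presence_only.value
        assert row["n_peptides_used"] == scalar.n_peptides_used


def test_abundance_per_sample():
    tbl = _table({"p1": ([10.0], []), "p2": ([30.0], [])})
    assert protein_abundance_per_sample(tbl, "case0") == 40.0
    assert math.isnan(protein_abundance_per_sample(tbl, "ctrl0"))
    one = _table({"p1": ([7.5], [])})
    assert protein_abundance_per_sample(one, "case0") == 7.5


def test_quant_config_validation():
    with pytest.raises(ValueError):
        QuantConfig(ratio_ceiling=0.5)
    with pytest.raises(ValueError):
        QuantConfig(p_floor=0.0)
    assert QuantConfig(ratio_ceiling=50).ratio_floor == pytest.approx(0.02)
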