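"""Abundance ratios, artificial exchanges, and bound parameterization."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from difflux import (
    AbundanceTable,
    MetaboliteMap,
    compute_ratios,
    ensure_exchanges,
    parameterize,
    pfba,
    validate_model,
)
from difflux.metabolomics import RatioTable, synthetic_exchange_id


def make_table(values_by_met, n_rep=3, conditions=("ctrl", "ko")):
    """values_by_met: met -> (t0_value, t20_value); replicates identical."""
    columns, meta = [], []
    data = {m: [] for m in values_by_met}
    for cond in conditions:
        for tp in (0.0, 20.0):
            for rep in range(1, n_rep + 1):
                s = f"{cond}_t{tp:g}_r{rep}"
                columns.append(s)
                meta.append(
                    {"sample": s, "condition": cond, "timepoint_h": tp, "replicate": rep}
                )
                for m, (v0, v20) in values_by_met.items():
                    data[m].append(v0 if tp == 0.0 else v20)
    values = pd.DataFrame(
        {s: [data[m][i] for m in values_by_met] for i, s in enumerate(columns)},
        index=pd.Index(list(values_by_met), name="metabolite"),
    )
    return AbundanceTable(values, pd.DataFrame(meta).set_index("sample"))


class TestComputeRatios:
    def test_mean_ratio(self):
        table = make_table({"glucose": (2.0, 4.0)})
        ratios = compute_ratios(table)
        assert ratios.ratio("ctrl", "glucose") == pytest.approx(2.0)

    def test_identity(self):
        table = make_table({"glucose": (3.0, 3.0)})
        assert compute_ratios(table).ratio("ko", "glucose") == pytest.approx(1.0)

    def test_zero_denominator_drops_metabolite(self, caplog):
        table = make_table({"glucose": (0.0, 4.0), "serine": (1.0, 2.0)})
        with caplog.at_level(logging.WARNING):
            ratios = compute_ratios(table)
        assert ratios.ratio("ctrl", "glucose") is None
        assert ratios.ratio("ctrl", "serine") == pytest.approx(2.0)
        assert any("glucose" in r[1] for r in [(c, m) for c, m, _ in ratios.dropped])
        assert "glucose" in caplog.text

    def test_missing_timepoint_is_an_error(self):
        table = make_table({"glucose": (2.0, 4.0)})
        keep = table.sample_meta["timepoint_h"] != 0.0
        broken = AbundanceTable(
            table.values[table.sample_meta.index[keep]],
            table.sample_meta[keep],
        )
        with pytest.raises(ValueError, match="timepoint"):
            compute_ratios(broken)

    def test_sample_permutation_invariance(self):
        table = make_table({"glucose": (2.0, 5.0), "serine": (1.0, 0.5)})
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.values.columns)
        shuffled = AbundanceTable(
            table.values[perm], table.sample_meta.loc[perm]
        )
        a = compute_ratios(table).data.set_index(["condition", "metabolite"])["ratio"]
        b = compute_ratios(shuffled).data.set_index(["condition", "metabolite"])["ratio"]
        assert a.sort_index().equals(b.sort_index())

    def test_ratio_clipping(self):
        table = make_table({"glucose": (1.0, 8.0)})
        assert compute_ratios(table, ratio_max=4.0).ratio("ctrl", "glucose") == 4.0


class TestEnsureExchanges:
    def test_adds_only_missing_exchange(self, toy_model, toy_mapping):
        out = ensure_exchanges(toy_model, toy_mapping)
        assert out.has_reaction(synthetic_exchange_id("akg"))
        added = out.get_reaction("EX_akg_synthetic")
        assert added.is_artificial and added.is_exchange
        assert added.bounds == (-out.default_bound, out.default_bound)
        assert added.subsystem == "Exchange"
        # mapped metabolites that already had exchanges are untouched
        assert len(out.reactions) == len(toy_model.reactions) + 1
        assert validate_model(out).errors == []

    def test_idempotent(self, toy_model, toy_mapping):
        once = ensure_exchanges(toy_model, toy_mapping)
        twice = ensure_exchanges(once, toy_mapping)
        assert twice.reaction_ids == once.reaction_ids

    def test_unknown_target_is_an_error(self, toy_model):
        with pytest.raises(ValueError, match="ghost"):
            ensure_exchanges(toy_model, MetaboliteMap({"x": "ghost"}))


import functools

from difflux import build_toy_model, toy_metabolite_map


@functools.lru_cache(maxsize=1)
def _cached_reference():
    mapping = MetaboliteMap(toy_metabolite_map())
    base = ensure_exchanges(build_toy_model(), mapping)
    return base, pfba(base), mapping


def ratio_table(entries):
    rows = [
        {
            "condition": c,
            "metabolite": m,
            "mean_den": 1.0,
            "mean_num": r,
            "n_den": 3,
            "n_num": 3,
            "ratio": r,
        }
        for (c, m), r in entries.items()
    ]
    return RatioTable(data=pd.DataFrame(rows))


class TestParameterize:
    @pytest.fixture
    def setup(self, toy_model, toy_mapping):
        base = ensure_exchanges(toy_model, toy_mapping)
        reference = pfba(base)  # EX_glc reference flux is -5
        return base, reference

    @pytest.mark.parametrize("ratio,expected_lb", [(2.0, -10.0), (0.5, -2.5)])
    def test_uptake_bound_scaling(self, setup, toy_mapping, ratio, expected_lb):
        base, reference = setup
        ratios = ratio_table(
            {("ko", name): (ratio if name == "glucose" else 1.0) for name in toy_mapping.entries}
        )
        out = parameterize(base, reference, ratios, "ko", toy_mapping)
        ex = out.get_reaction("EX_glc")
        assert ex.lower_bound == pytest.approx(expected_lb)
        assert ex.upper_bound == base.get_reaction("EX_glc").upper_bound

    def test_zero_reference_policies(self, setup, toy_mapping):
        base, reference = setup
        assert abs(reference["EX_lac"]) < 1e-9  # lactate unused at reference
        ratios = ratio_table({("ko", n): 3.0 for n in toy_mapping.entries})
        leave = parameterize(base, reference, ratios, "ko", toy_mapping)
        assert leave.get_reaction("EX_lac").bounds == base.get_reaction("EX_lac").bounds
        assert "lactate" in leave.notes["parameterization"]["zero_reference"]
        clamp = parameterize(
            base, reference, ratios, "ko", toy_mapping, zero_reference_policy="clamp"
        )
        assert clamp.get_reaction("EX_lac").bounds == (0.0, 0.0)
        eps = parameterize(
            base, reference, ratios, "ko", toy_mapping, zero_reference_policy="epsilon"
        )
        lo, hi = eps.get_reaction("EX_lac").bounds
        assert lo == pytest.approx(-1e-6 * base.default_bound) and hi == -lo

    def test_absent_condition_is_an_error(self, setup, toy_mapping):
        base, reference = setup
        ratios = ratio_table({("ko", n): 1.0 for n in toy_mapping.entries})
        with pytest.raises(ValueError, match="'ctrl'"):
            parameterize(base, reference, ratios, "ctrl", toy_mapping)

    @hsettings(max_examples=20, derandomize=True, deadline=None)
    @given(ratio=st.floats(min_value=1e-3, max_value=1e3))
    def test_sign_preservation(self, ratio):
        """No exchange flips between uptake-capable and secretion-only."""
        base, reference, mapping = _cached_reference()
        ratios = ratio_table({("ko", n): ratio for n in mapping.entries})
        out = parameterize(base, reference, ratios, "ko", mapping)
        for before, after in zip(base.reactions, out.reactions):
            assert (before.lower_bound < 0) == (after.lower_bound < 0) or (
                after.lower_bound == 0
            )
            assert (before.upper_bound > 0) == (after.upper_bound > 0) or (
                after.upper_bound == 0
            )
            assert after.lower_bound <= after.upper_bound


class TestFileFormats:
    def test_abundance_round_trip(self, tmp_path):
        table = make_table({"glucose": (2.0, 4.0), "serine": (1.0, 1.5)})
        table.to_tsv(tmp_path / "ab.tsv", tmp_path / "meta.tsv")
        again = AbundanceTable.from_tsv(tmp_path / "ab.tsv", tmp_path / "meta.tsv")
        pd.testing.assert_frame_equal(again.values, table.values)
        assert list(again.sample_meta["condition"]) == list(
            table.sample_meta["condition"]
        )

    def test_mapping_round_trip(self, tmp_path, toy_mapping):
        toy_mapping.to_tsv(tmp_path / "map.tsv")
        again = MetaboliteMap.from_tsv(tmp_path / "map.tsv")
        assert again.entries == toy_mapping.entries

    def test_ratio_tsv_columns_carry_timepoints(self, tmp_path):
        table = make_table({"glucose": (2.0, 4.0)})
        ratios = compute_ratios(table)
        ratios.to_tsv(tmp_path / "ratios.tsv")
        header = (tmp_path / "ratios.tsv").read_text().splitlines()[0].split("\t")
        assert header == [
            "condition",
            "metabolite",
            "mean_t0",
            "mean_t20",
            "n_t0",
            "n_t20",
            "ratio",
        ]
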