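"""Drug-response categorization, pan-calls, radiotherapy and dependency rules."""

import numpy as np
import pandas as pd
import pytest

from mirdx.errors import ValidationError
from mirdx.pharmaco import (PanCall, categorize_lines, gene_drug_call,
                            normalize_dependency, pan_call,
                            proliferation_profile, radiotherapy_call,
                            responder_genes)
from mirdx.simulate import DependencyScreen, gen_pharmaco_panel


def _panel(values, drug="d1", measure="ln_IC50", source="src"):
    return pd.DataFrame({
        "cell_line": [f"c{i}" for i in range(len(values))],
        "drug": drug, "measure": measure, "value": values, "source": source})


class TestCategorizeLines:
    def test_nine_lines_tertile_oracle(self):
        cat = categorize_lines(_panel(list(range(1, 10))))
        by_line = cat.set_index("cell_line")["category"]
        # oracle by sorting: lowest 3 sensitive, highest 3 resistant
        assert list(by_line[[f"c{i}" for i in range(3)]]) == ["sensitive"] * 3
        assert list(by_line[[f"c{i}" for i in range(6, 9)]]) == ["resistant"] * 3
        assert list(by_line[[f"c{i}" for i in range(3, 6)]]) == ["excluded"] * 3

    def test_identical_values_all_excluded(self):
        cat = categorize_lines(_panel([2.0] * 9))
        assert (cat["category"] == "excluded").all()

    def test_five_lines_all_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            cat = categorize_lines(_panel([1, 2, 3, 4, 5]))
        assert (cat["category"] == "excluded").all()
        assert any("excluded" in r.message for r in caplog.records)

    def test_groups_independent_across_sources(self):
        panel = pd.concat([_panel(list(range(9)), source="s1"),
                           _panel(list(range(9, 0, -1)), source="s2")])
        cat = categorize_lines(panel)
        s1 = cat[cat["source"] == "s1"].set_index("cell_line")["category"]
        s2 = cat[cat["source"] == "s2"].set_index("cell_line")["category"]
        assert s1["c0"] == "sensitive" and s2["c0"] == "resistant"


class TestGeneDrugCall:
    @staticmethod
    def _setup(delta, seed=0, n=12):
        rng = np.random.default_rng(seed)
        lines = [f"c{i}" for i in range(2 * n)]
        panel = _panel(list(range(2 * n)))
        panel["cell_line"] = lines
        cat = categorize_lines(panel)
        sens = cat.loc[cat["category"] == "sensitive", "cell_line"]
        expr = pd.DataFrame(rng.normal(0, 0.5, size=(1, 2 * n)),
                            index=["g"], columns=lines)
        expr.loc["g", sens] += delta
        return expr, cat

    def test_higher_in_sensitive_called_sensitive(self):
        expr, cat = self._setup(3.0)
        assert gene_drug_call(expr, cat, "d1").loc["g", "call"] == "sensitive"

    def test_higher_in_resistant_called_resistant(self):
        expr, cat = self._setup(-3.0)
        assert gene_drug_call(expr, cat, "d1").loc["g", "call"] == "resistant"

    def test_no_difference_neutral(self):
        expr, cat = self._setup(0.0)
        assert gene_drug_call(expr, cat, "d1").loc["g", "call"] == "neutral"

    def test_insufficient_lines_neutral_flagged(self):
        expr, cat = self._setup(3.0)
        expr = expr[expr.columns[:3]]
        out = gene_drug_call(expr, cat, "d1")
        assert out.loc["g", "call"] == "neutral"
        assert out.loc["g", "flag"] == "insufficient_lines"

    def test_conflicting_sources_veto_to_neutral(self):
        rng = np.random.default_rng(1)
        n = 9
        lines = [f"c{i}" for i in range(n)]
        p1 = _panel(list(range(n)), source="s1")
        p2 = _panel(list(range(n - 1, -1, -1)), source="s2")
        cat = categorize_lines(pd.concat([p1, p2], ignore_index=True))
        expr = pd.DataFrame(rng.normal(0, 0.3, (1, n)), index=["g"],
                            columns=lines)
        expr.loc["g", ["c0", "c1", "c2"]] += 4.0  # sensitive in s1, resistant in s2
        out = gene_drug_call(expr, cat, "d1")
        assert out.loc["g", "call"] == "neutral"
        assert out.loc["g", "flag"] == "source_conflict"


class TestPanCall:
    N_DRUGS = 21

    @classmethod
    def _calls(cls, mapping):
        base = {f"d{i}": "neutral" for i in range(cls.N_DRUGS)}
        base.update(mapping)
        return base

    def test_single_sensitive_drug_both_layers_pansensitive(self):
        layers = {"mRNA": self._calls({"d3": "sensitive"}),
                  "protein": self._calls({"d3": "sensitive"})}
        assert pan_call("DGKE-like", layers, ["mRNA", "protein"]).call == "pansensitive"

    def test_resistant_pattern_both_layers_panresistant(self):
        res = {"d0": "resistant", "d1": "resistant", "d2": "resistant"}
        layers = {"mRNA": self._calls(res), "protein": self._calls(res)}
        assert pan_call("WDR47-like", layers, ["mRNA", "protein"]).call == "panresistant"

    def test_neutral_everywhere_is_neither(self):
        layers = {"mRNA": self._calls({}), "protein": self._calls({})}
        assert pan_call("g", layers, ["mRNA", "protein"]).call == "neither"

    def test_single_layer_resistance_blocks_pansensitive(self):
        layers = {"mRNA": self._calls({"d3": "sensitive", "d7": "resistant"}),
                  "protein": self._calls({"d3": "sensitive"})}
        assert pan_call("g", layers, ["mRNA", "protein"]).call == "neither"

    def test_missing_layer_flagged(self):
        layers = {"mRNA": self._calls({"d3": "sensitive"})}
        out = pan_call("g", layers, ["mRNA", "protein"])
        assert out.call == "neither"
        assert "missing" in out.flag

    def test_mirna_single_layer_rule(self):
        layers = {"miRNA": self._calls({"d0": "sensitive", "d5": "sensitive"})}
        assert pan_call("miR", layers, ["miRNA"]).call == "pansensitive"

    def test_truth_table_mutual_exclusivity_sampled(self):
        """10^4 random call vectors plus boundary vectors: pansensitive and
        panresistant never co-occur and removing a drug never flips the call
        from pansensitive to panresistant."""
        rng = np.random.default_rng(9)
        states = np.array(["sensitive", "resistant", "neutral"])
        boundary = [
            {f"d{i}": "neutral" for i in range(self.N_DRUGS)},
            {f"d{i}": "sensitive" for i in range(self.N_DRUGS)},
            {f"d{i}": "resistant" for i in range(self.N_DRUGS)},
        ]
        vectors = [dict(zip([f"d{i}" for i in range(self.N_DRUGS)], v))
                   for v in states[rng.integers(0, 3, size=(10_000, self.N_DRUGS))]]
        for calls in boundary + vectors:
            out = pan_call("g", {"miRNA": calls}, ["miRNA"])
            assert out.call in ("pansensitive", "panresistant", "neither")
            if out.call == "pansensitive":
                assert "resistant" not in calls.values()
                assert "sensitive" in calls.values()
            if out.call == "panresistant":
                assert "sensitive" not in calls.values()
            # drop one drug: never flips between the two pan categories
            reduced = dict(list(calls.items())[:-1])
            out2 = pan_call("g", {"miRNA": reduced}, ["miRNA"])
            assert not (out.call == "pansensitive" and out2.call == "panresistant")
            assert not (out.call == "panresistant" and out2.call == "pansensitive")

    def test_planted_panel_recovery_over_seeds(self):
        """Linked genes recover their planted pan direction; unlinked genes
        stay neither, in >= 90% of seeds."""
        ok_link, ok_null, N = 0, 0, 10
        for seed in range(N):
            panel, mrna, prot = gen_pharmaco_panel(
                60, 21, {"S": ("drug00", "sensitive"),
                         "R": ("drug05", "resistant")},
                seed=seed, n_background=2)
            cat = categorize_lines(panel)
            drugs = sorted(cat["drug"].unique())
            calls = {}
            for ly, expr in (("mRNA", mrna), ("protein", prot)):
                per = {d: gene_drug_call(expr, cat, d) for d in drugs}
                calls[ly] = {g: {d: per[d].loc[g, "call"] for d in drugs}
                             for g in expr.index}
            layered = lambda g: {ly: calls[ly][g] for ly in calls}
            ok_link += (pan_call("S", layered("S"), ["mRNA", "protein"]).call
                        == "pansensitive"
                        and pan_call("R", layered("R"), ["mRNA", "protein"]).call
                        == "panresistant")
            ok_null += all(
                pan_call(g, layered(g), ["mRNA", "protein"]).call == "neither"
                for g in ("GENE000", "GENE001"))
        assert ok_link / N >= 0.9
        assert ok_null / N >= 0.9


class TestRadiotherapyCall:
    @staticmethod
    def _cohort(seed=0):
        rng = np.random.default_rng(seed)
        n_long, n_short, n_mid = 5, 20, 6
        ids = [f"p{i}" for i in range(n_long + n_short + n_mid)]
        times = ([80.0 + i for i in range(n_long)]
                 + [5.0 + i * 0.5 for i in range(n_short)]
                 + [30.0 + i for i in range(n_mid)])
        meta = pd.DataFrame({
            "class_label": "tumor", "pair_id": None,
            "histology": "NSCLC",
            "stage": ["III"] * len(ids),
            "radiotherapy": True, "time_months": times,
            "event": True}, index=pd.Index(ids, name="sample_id"))
        expr = pd.DataFrame(rng.normal(0, 1, size=(2, len(ids))),
                            index=["resp", "flat"], columns=ids)
        expr.loc["resp", ids[:n_long]] += 4.0  # higher in long survivors
        return expr, meta

    def test_long_survival_gene_rt_sensitive(self):
        expr, meta = self._cohort()
        out = radiotherapy_call(expr, meta)
        assert out.loc["resp", "call"] == "rt_sensitive"
        assert out.loc["flat", "call"] == "neutral"
        assert out.loc["resp", "n_long"] == 5
        assert out.loc["resp", "n_short"] == 20

    def test_boundary_patients_excluded(self):
        expr, meta = self._cohort()
        meta.loc["p0", "time_months"] = 58.0  # exactly at boundary: excluded
        out = radiotherapy_call(expr, meta)
        assert out.loc["resp", "n_long"] == 4

    def test_short_survival_gene_rt_resistant(self):
        expr, meta = self._cohort()
        expr.loc["resp"] *= -1
        assert radiotherapy_call(expr, meta).loc["resp", "call"] == "rt_resistant"

    def test_insufficient_group_rejected(self):
        expr, meta = self._cohort()
        meta.loc[meta["time_months"] > 58, "time_months"] = 40.0
        with pytest.raises(ValidationError, match="group"):
            radiotherapy_call(expr, meta)


class TestNormalizeDependency:
    @staticmethod
    def _screen(raw, ess=("E0",), non=("N0",)):
        return DependencyScreen(assay="CRISPR", raw=raw,
                                essential_ids=list(ess),
                                nonessential_ids=list(non))

    def test_anchor_values_and_threshold_boundary(self):
        # line with m_ess=-2, m_non=1: x=1 -> 0, x=-2 -> -1, x=-0.5 -> -0.5
        raw = pd.DataFrame({"L": [-2.0, 1.0, -0.5]},
                           index=["E0", "N0", "g"])
        screen = normalize_dependency(self._screen(raw))
        assert screen.normalized.loc["E0", "L"] == pytest.approx(-1.0, abs=1e-12)
        assert screen.normalized.loc["N0", "L"] == pytest.approx(0.0, abs=1e-12)
        assert screen.normalized.loc["g", "L"] == pytest.approx(-0.5, abs=1e-12)
        # strictly-less-than rule: exactly -0.5 is NOT significant
        assert not (screen.normalized.loc["g", "L"] < -0.5)

    def test_exact_anchor_medians_many_lines(self):
        rng = np.random.default_rng(0)
        ess = [f"E{i}" for i in range(7)]
        non = [f"N{i}" for i in range(7)]
        raw = pd.DataFrame(rng.normal(0, 1, size=(20, 9)),
                           index=ess + non + [f"g{i}" for i in range(6)],
                           columns=[f"L{i}" for i in range(9)])
        screen = normalize_dependency(self._screen(raw, ess, non))
        assert np.allclose(screen.normalized.loc[ess].median(axis=0), -1.0,
                           atol=1e-9)
        assert np.allclose(screen.normalized.loc[non].median(axis=0), 0.0,
                           atol=1e-9)

    def test_unique_affine_map(self):
        """Any affine map hitting both anchors equals the implemented one."""
        raw = pd.DataFrame({"L": [-3.0, 0.5, 1.2, -1.7]},
                           index=["E0", "N0", "a", "b"])
        screen = normalize_dependency(self._screen(raw))
        m_ess, m_non = -3.0, 0.5
        a = 1.0 / (m_non - m_ess)
        b = -m_non / (m_non - m_ess)
        assert np.allclose(screen.normalized["L"], a * raw["L"] + b)

    def test_degenerate_line_named(self):
        raw = pd.DataFrame({"good": [-2.0, 1.0], "bad": [0.3, 0.3]},
                           index=["E0", "N0"])
        with pytest.raises(ValidationError, match="bad"):
            normalize_dependency(self._screen(raw))


class TestProliferationProfile:
    @staticmethod
    def _screen_with_fractions(frac, assay, n_lines=10, seed=0):
        ess, non = ["E0"], ["N0"]
        n_hit = int(round(frac * n_lines))
        row = np.zeros(n_lines)
        row[:n_hit] = -0.9
        raw = pd.DataFrame(
            np.vstack([np.full(n_lines, -1.0), np.zeros(n_lines), row]),
            index=["E0", "N0", "g"], columns=[f"L{i}" for i in range(n_lines)])
        # tiny jitter so anchor medians stay distinct but exact
        screen = DependencyScreen(assay=assay, raw=raw, essential_ids=ess,
                                  nonessential_ids=non)
        return normalize_dependency(screen)

    @pytest.mark.parametrize("f1,f2,expected", [
        (0.8, 0.6, "both_major"),
        (0.8, 0.2, "either_major"),
        (0.0, 0.0, "none_significant"),
        (0.3, 0.2, "other"),
    ])
    def test_classes(self, f1, f2, expected):
        screens = [self._screen_with_fractions(f1, "CRISPR"),
                   self._screen_with_fractions(f2, "RNAi")]
        prof = proliferation_profile(screens, ["g"])["g"]
        assert prof.profile_class == expected
        assert prof.fraction_significant["CRISPR"] == pytest.approx(f1)
        assert prof.fraction_significant["RNAi"] == pytest.approx(f2)

    def test_gene_missing_from_one_assay_flagged(self):
        s1 = self._screen_with_fractions(0.8, "CRISPR")
        s2 = self._screen_with_fractions(0.8, "RNAi")
        s2.normalized = s2.normalized.drop("g")
        prof = proliferation_profile([s1, s2], ["g"])["g"]
        assert prof.flag == "missing_assay"
        assert prof.profile_class == "both_major"  # on the available assay


class TestResponderGenes:
    def test_concordance_filter(self):
        rng = np.random.default_rng(3)
        n = 18
        lines = [f"c{i}" for i in range(n)]
        panel = _panel(list(range(n)), drug="bx")
        panel["cell_line"] = lines
        cat = categorize_lines(panel)
        sens = cat.loc[cat["category"] == "sensitive", "cell_line"]
        mrna = pd.DataFrame(rng.normal(0, 0.5, (3, n)),
                            index=["both", "mrna_only", "opposite"],
                            columns=lines)
        prot = pd.DataFrame(rng.normal(0, 0.5, (3, n)),
                            index=mrna.index, columns=lines)
        mrna.loc["both", sens] += 3.0
        prot.loc["both", sens] += 3.0
        mrna.loc["mrna_only", sens] += 3.0
        mrna.loc["opposite", sens] += 3.0
        prot.loc["opposite", sens] -= 3.0
        out = responder_genes(mrna, prot, cat, "bx")
        assert list(out.index) == ["both"]
        assert out.loc["both", "direction"] == "sensitive"
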