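"""Synthetic cohort generator: determinism, planted effects, round-trip I/O."""

import numpy as np
import pytest

from assortnet import (
    SyntheticConfig,
    feature_matrix,
    generate_bold_panel,
    generate_cohort,
    global_assortativity,
    partial_correlation_network,
    read_cohort,
    write_cohort,
)
from assortnet.exceptions import CohortIOError, ConfigError


class TestConfig:
    def test_overlapping_planted_sets_rejected(self):
        with pytest.raises(ConfigError, match="disjoint"):
            SyntheticConfig(hypo_nodes=(1, 2), hyper_nodes=(2, 3))

    def test_out_of_range_node_ids_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(node_count=10, hypo_nodes=(12,), hyper_nodes=())

    def test_group_sizes_validated(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(group_sizes=(1, 5, 5))

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("node_count: 30\ngroup_sizes: [4, 5, 3]\n"
                     "hypo_nodes: [2, 9]\nhyper_nodes: [5, 14]\nseed: 3\n")
        cfg = SyntheticConfig.from_file(p)
        assert cfg.node_count == 30 and cfg.group_sizes == (4, 5, 3) and cfg.seed == 3


class TestGeneration:
    def test_determinism(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        assert a.subject_ids == b.subject_ids
        assert np.array_equal(a.ages, b.ages)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.snet.adjacency, sb.snet.adjacency)
            np.testing.assert_array_equal(sa.fnet.adjacency, sb.fnet.adjacency)

    def test_demographics(self, default_cohort):
        g = default_cohort.groups
        assert [(g == x).sum() for x in ("SCI", "MCI", "ADD")] == [24, 46, 18]
        assert np.all((default_cohort.ages >= 40) & (default_cohort.ages <= 95))
        # ADD subjects are oldest on average, as in the study
        assert default_cohort.ages[g == "ADD"].mean() > default_cohort.ages[g == "SCI"].mean()
        sexes = {s.sex for s in default_cohort.subjects}
        assert sexes == {"F", "M"}

    def test_structural_functional_assortativity_dichotomy(self, default_cohort):
        rs = np.median([global_assortativity(s.snet) for s in default_cohort.subjects])
        rf = np.median([global_assortativity(s.fnet) for s in default_cohort.subjects])
        assert rs > 0 > rf

    def test_realized_planted_shift_near_one_sd(self, default_cohort):
        """Mean planted shift across nodes stays within 25% of effect_size."""
        cfg = default_cohort.config
        na = feature_matrix(default_cohort, "NA", "structural")
        g = na.groups
        shifts = []
        for nodes, (ga, gb), sign in ((cfg.hypo_nodes, ("SCI", "MCI"), -1),
                                      (cfg.hyper_nodes, ("MCI", "ADD"), +1)):
            A = na.values[g == ga][:, list(nodes)]
            B = na.values[g == gb][:, list(nodes)]
            pooled = np.sqrt((A.var(axis=0, ddof=1) + B.var(axis=0, ddof=1)) / 2)
            shifts.extend(sign * (B.mean(0) - A.mean(0)) / pooled)
        mean_shift = np.mean(shifts)
        assert 0.75 * cfg.effect_size <= mean_shift <= 1.25 * cfg.effect_size

    def test_null_config_plants_nothing(self, small_config):
        from dataclasses import replace

        null_cfg = replace(small_config, effect_size=0.0)
        coh = generate_cohort(null_cfg)
        na = feature_matrix(coh, "NA", "structural")
        g = na.groups
        # planted nodes shift less than one baseline sd between any groups
        for v in small_config.hypo_nodes:
            sci = na.values[g == "SCI", v]
            mci = na.values[g == "MCI", v]
            assert abs(mci.mean() - sci.mean()) < 3 * sci.std(ddof=1)


class TestBoldPanel:
    def test_determinism_and_shape(self, small_cohort):
        s = small_cohort.subjects[0]
        a = generate_bold_panel(small_cohort.config, s, timepoints=200, seed=5)
        b = generate_bold_panel(small_cohort.config, s, timepoints=200, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (small_cohort.node_count, 200)

    def test_panel_recovers_functional_support(self):
        """Close the loop: generator -> BOLD panel -> partial-correlation net."""
        cfg = SyntheticConfig(seed=11, node_count=20, group_sizes=(3, 3, 3),
                              hypo_nodes=(), hyper_nodes=(), base_density=0.15)
        coh = generate_cohort(cfg)
        s = coh.subjects[0]
        true_support = np.abs(s.fnet.adjacency[np.triu_indices(20, 1)]) > 0
        panel = generate_bold_panel(cfg, s, timepoints=200, seed=12)
        net = partial_correlation_network(panel)
        est_support = np.abs(net.adjacency[np.triu_indices(20, 1)]) > 1e-8
        from sklearn.metrics import matthews_corrcoef

        assert matthews_corrcoef(true_support, est_support) > 0.6


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "mtx"])
    def test_write_read_identity(self, small_cohort, tmp_path, fmt):
        d = tmp_path / fmt
        write_cohort(small_cohort, d, fmt=fmt)
        back = read_cohort(d)
        assert back.subject_ids == small_cohort.subject_ids
        assert np.array_equal(back.groups, small_cohort.groups)
        np.testing.assert_allclose(back.ages, small_cohort.ages, atol=1e-12)
        for sa, sb in zip(small_cohort.subjects, back.subjects):
            np.testing.assert_allclose(sa.snet.adjacency, sb.snet.adjacency, atol=1e-12)
            np.testing.assert_allclose(sa.fnet.adjacency, sb.fnet.adjacency, atol=1e-12)

    def test_bold_panels_round_trip(self, small_cohort, tmp_path):
        from dataclasses import replace as dc_replace

        sid = small_cohort.subject_ids[0]
        panel = generate_bold_panel(small_cohort.config, small_cohort.subjects[0],
                                    timepoints=30, seed=2)
        coh = dc_replace(small_cohort, bold_panels={sid: panel})
        write_cohort(coh, tmp_path)
        back = read_cohort(tmp_path)
        np.testing.assert_allclose(back.bold_panels[sid], panel, atol=1e-12)

    def test_missing_adjacency_names_subject(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        victim = small_cohort.subject_ids[3]
        (tmp_path / "snet" / f"{victim}.csv").unlink()
        with pytest.raises(CohortIOError, match=victim):
            read_cohort(tmp_path)

    def test_malformed_participants_reports_line(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        part = tmp_path / "participants.tsv"
        lines = part.read_text().splitlines()
        lines[2] = "broken\trow"
        part.write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortIOError, match=":3:"):
            read_cohort(tmp_path)
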