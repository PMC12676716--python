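import numpy as np
import pytest

from schoco import pipeline as pl
from schoco.simulate import (
    CONTROL,
    PRESETS,
    TREATED,
    beta_from_mean_sd,
    make_community,
    simulate_cell,
    simulate_paired_dataset,
    write_dataset,
)
from schoco.formats import read_asv_table


class TestBetaMomentMatching:
    def test_mean_and_sd_recovered(self):
        a, b = beta_from_mean_sd(0.714, 0.143)
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.714)
        assert np.sqrt(var) == pytest.approx(0.143)

    def test_impossible_sd_rejected(self):
        with pytest.raises(ValueError):
            beta_from_mean_sd(0.5, 0.6)


class TestMakeCommunity:
    def test_single_taxon_has_unit_abundance(self):
        com = make_community("A1", 1, 1.0, seed=0)
        assert com.n_taxa == 1
        assert com.taxa[0][1] == pytest.approx(1.0)

    def test_abundances_normalised(self):
        com = make_community("A1", 20, 2.0, seed=1)
        assert sum(w for _, w in com.taxa) == pytest.approx(1.0)

    def test_two_strains_share_exactly_core_genera(self):
        a = make_community("A1", 15, 1.0, seed=0)
        b = make_community("A2", 15, 1.0, seed=0)
        shared = {t.split(".", 1)[1] for t, _ in a.taxa} & {
            t.split(".", 1)[1] for t, _ in b.taxa
        }
        assert len(shared) == 8

    def test_near_uniform_at_tiny_sigma(self):
        com = make_community("A1", 10, 1e-6, seed=0, core_frac=None)
        weights = [w for _, w in com.taxa]
        assert max(weights) / min(weights) == pytest.approx(1.0, abs=1e-4)


class TestSimulateCell:
    def test_full_efficiency_removes_chloroplast(self):
        preset = PRESETS["tgravida-a1"]
        from dataclasses import replace

        p = replace(preset, efficiency=1.0)
        counts, tax, meta, truth = simulate_cell(
            p, cell_id="x1", treatment=TREATED, seed=4
        )
        assert counts["chl.A1"] == 0

    def test_zero_efficiency_treated_matches_control_distribution(self):
        from dataclasses import replace

        p = replace(PRESETS["tgravida-a1"], efficiency=0.0)
        c_counts, *_ = simulate_cell(p, cell_id="x1", treatment=CONTROL,
                                     seed=4)
        t_counts, _, _, truth = simulate_cell(p, cell_id="x1",
                                              treatment=TREATED, seed=4)
        # same template proportions; only depth/multinomial noise differs
        c_truth = simulate_cell(p, cell_id="x1", treatment=CONTROL,
                                seed=4)[3]
        assert truth["template_proportions"] == c_truth[
            "template_proportions"
        ]

    def test_control_mean_chloroplast_matches_preset(self):
        preset = PRESETS["tgravida-a1"]
        fracs = []
        for i in range(400):
            counts, *_ , truth = simulate_cell(
                preset, cell_id=f"m{i}", treatment=CONTROL, seed=9
            )
            fracs.append(truth["chl_fraction_pre"])
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - preset.chl_mean) <= 3 * se


class TestPairedDataset:
    def test_shape_and_pairing(self):
        table, ledger = simulate_paired_dataset("tgravida-a1", seed=3,
                                                n_cells=62)
        assert len(table.sample_ids) == 124
        cells = {m.cell_id for m in table.samples.values()}
        assert len(cells) == 62
        for cell, arms in ledger["cells"].items():
            assert set(arms) == {CONTROL, TREATED}
            assert arms[CONTROL]["chl_fraction_pre"] == arms[TREATED][
                "chl_fraction_pre"
            ]

    def test_ledger_matches_column_composition(self):
        table, ledger = simulate_paired_dataset("tgravida-a1", seed=5,
                                                n_cells=3)
        for cell, arms in ledger["cells"].items():
            truth = arms[CONTROL]
            sid = f"{cell}.C"
            assert table.counts[sid].sum() == truth["depth"]
            pi = truth["template_proportions"]
            assert sum(pi.values()) == pytest.approx(1.0)

    def test_cell_streams_independent_of_ordering(self):
        t1, _ = simulate_paired_dataset("tgravida-a1", seed=8, n_cells=5)
        t2, _ = simulate_paired_dataset("tgravida-a1", seed=8, n_cells=3)
        shared = t2.sample_ids
        assert t1.counts[shared].equals(t2.counts[shared])

    def test_closed_form_post_depletion_matches_treated_means(self):
        table, ledger = simulate_paired_dataset("tgravida-a1", seed=11,
                                                n_cells=62)
        calls = pl.classify_asvs(table)
        props = pl.category_proportions(table, calls)
        trt = [s for s in props.index
               if table.samples[s].treatment == TREATED]
        got = props.loc[trt, "chloroplast"].mean() / 100
        expect = ledger["expected_post_chl_closed_form"]
        sd = props.loc[trt, "chloroplast"].std() / 100
        assert abs(got - expect) <= 3 * sd / np.sqrt(len(trt))

    def test_richness_lift_positive_with_a1_preset(self):
        wins = 0
        for s in range(1, 11):
            table, _ = simulate_paired_dataset("tgravida-a1", seed=s)
            res = pl.run_pipeline(table, seed=s)
            contrast = pl.richness_contrast(res.richness,
                                            res.filtered.samples)
            wins += contrast.mean_lift_pct > 0
        assert wins >= 10 * 0.95

    def test_roundtrip_through_tsv(self, tmp_path):
        table, ledger = simulate_paired_dataset("tgravida-a1", seed=2,
                                                n_cells=2)
        write_dataset(table, ledger, tmp_path)
        back = read_asv_table(tmp_path / "counts.tsv",
                              tmp_path / "taxonomy.tsv",
                              tmp_path / "metadata.tsv")
        assert back.counts.equals(table.counts)
        calls = pl.classify_asvs(back)
        assert calls["chl.A1"] == "chloroplast"
        assert calls["mito.A1"] == "mitochondria"


class TestToyRefDb:
    def test_planted_mismatch_counts(self, toy_refdb):
        from schoco.guide_screen import SELECTED_SPACER, find_target_sites

        decoys = toy_refdb[1:]
        at2 = find_target_sites(SELECTED_SPACER, decoys, 2, True)
        assert sorted(h.seq_id for h in at2) == ["dec_chloro", "dec_mm1",
                                                 "dec_mm2"]
        at1 = find_target_sites(SELECTED_SPACER, decoys, 1, True)
        assert sorted(h.seq_id for h in at1) == ["dec_chloro", "dec_mm1"]

    def test_headers_parse_in_both_dialects(self, toy_refdb):
        assert toy_refdb[0].lineage.dialect == "phytoref"
        assert toy_refdb[0].lineage.contains("Thalassiosira")
        assert toy_refdb[1].lineage.dialect == "silva"
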