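"""Generator behavior: calibration of planted signals, determinism, and
agreement of closed-form joint tables with brute-force sampling."""

import dataclasses

import numpy as np
import pytest

from epinet import simulate
from epinet.errors import ConfigError
from epinet.ppi import merge, map_to_human, read_biogrid_tab, read_mitab, read_orthologs


# ---------------------------------------------------------------------------
# ESC tables


def test_null_table_has_equal_bait_and_control_means():
    cfg = simulate.EscSimConfig(
        n_proteins=4000, n_true_interactors=0, background_mean=5.0,
        enrichment_factor=1.0, detect_dropout=0.0, seed=3,
    )
    table, _ = simulate.generate_esc_table(cfg)
    bait = table.counts[table.bait_samples].to_numpy().mean()
    ctrl = table.counts[table.control_samples].to_numpy().mean()
    # each column mean is an average over n_proteins Poisson(5) draws
    se = np.sqrt(5.0 / (cfg.n_proteins * 3))
    assert abs(bait - ctrl) < 3 * np.sqrt(2) * se


def test_empty_table():
    cfg = simulate.EscSimConfig(n_proteins=0, n_true_interactors=0)
    table, truth = simulate.generate_esc_table(cfg)
    assert table.counts.shape == (0, 6)
    assert truth.true_interactor_ids == set()


def test_enriched_mean_matches_poisson_sampling_oracle():
    """Planted interactors in bait columns follow the count distribution with
    mean enrichment_factor * background_mean, checked against an independent
    brute-force draw of 1e5 Poisson variates."""
    cfg = simulate.EscSimConfig(
        n_proteins=2000, n_true_interactors=400, n_bait_reps=3,
        background_mean=3.0, enrichment_factor=10.0, detect_dropout=0.0, seed=9,
    )
    table, truth = simulate.generate_esc_table(cfg)
    cells = table.counts.loc[sorted(truth.true_interactor_ids), table.bait_samples]
    observed = cells.to_numpy(dtype=float)

    oracle = np.random.default_rng(12345).poisson(30.0, size=100_000)
    se_obs = observed.std() / np.sqrt(observed.size)
    se_oracle = oracle.std() / np.sqrt(oracle.size)
    assert abs(observed.mean() - oracle.mean()) < 4 * np.hypot(se_obs, se_oracle)
    assert abs(observed.mean() - 30.0) < 4 * se_obs


def test_dropout_forces_zeros():
    cfg = simulate.EscSimConfig(
        n_proteins=500, n_true_interactors=0, background_mean=50.0,
        detect_dropout=0.3, seed=5,
    )
    table, _ = simulate.generate_esc_table(cfg)
    frac_zero = (table.counts.to_numpy() == 0).mean()
    # Poisson(50) is never 0 in practice; zeros come from dropout alone
    assert abs(frac_zero - 0.3) < 4 * np.sqrt(0.3 * 0.7 / table.counts.size)


def test_overdispersion_inflates_variance():
    base = dict(n_proteins=3000, n_true_interactors=0, background_mean=20.0,
                enrichment_factor=1.0, detect_dropout=0.0, seed=8)
    pois, _ = simulate.generate_esc_table(simulate.EscSimConfig(**base))
    nb, _ = simulate.generate_esc_table(simulate.EscSimConfig(**base, dispersion=2.0))
    assert nb.counts.to_numpy().var() > 2 * pois.counts.to_numpy().var()


@pytest.mark.parametrize(
    "override, fieldname",
    [
        ({"n_true_interactors": 11, "n_proteins": 10}, "n_true_interactors"),
        ({"background_mean": 0.0}, "background_mean"),
        ({"detect_dropout": 1.5}, "detect_dropout"),
        ({"n_bait_reps": 1}, "n_bait_reps"),
        ({"enrichment_factor": 0.5}, "enrichment_factor"),
    ],
)
def test_esc_config_errors_name_the_field(override, fieldname):
    cfg = dataclasses.replace(simulate.EscSimConfig(), **override)
    with pytest.raises(ConfigError, match=fieldname):
        simulate.generate_esc_table(cfg)


def test_esc_determinism_bit_identical(tmp_path):
    cfg = simulate.EscSimConfig(n_proteins=200, n_true_interactors=20, seed=77)
    for sub in ("a", "b"):
        table, _ = simulate.generate_esc_table(cfg)
        simulate.write_esc_files(table, tmp_path / sub)
    assert (tmp_path / "a/esc_table.tsv").read_bytes() == (tmp_path / "b/esc_table.tsv").read_bytes()
    assert (tmp_path / "a/samples.tsv").read_bytes() == (tmp_path / "b/samples.tsv").read_bytes()


# ---------------------------------------------------------------------------
# dual-bait detections


def test_degenerate_marginal_gives_all_false():
    cfg = simulate.DualBaitSimConfig(n_interactors=500, prevalence_a=0.0,
                                     prevalence_b=0.4, seed=1)
    det, truth = simulate.generate_dual_bait_detections(cfg)
    assert not det["bait_a"].any()
    joint = np.array(truth.dual_bait_joint_probabilities)
    assert joint[1, 1] == 0.0


def test_independence_product_in_ground_truth():
    cfg = simulate.DualBaitSimConfig(n_interactors=10, prevalence_a=0.5,
                                     prevalence_b=0.5, dependence=0.0, seed=2)
    _, truth = simulate.generate_dual_bait_detections(cfg)
    joint = np.array(truth.dual_bait_joint_probabilities)
    assert joint[1, 1] == pytest.approx(0.25, abs=0)


def test_correlated_joint_table_closed_form_and_sampling_oracle():
    """dependence=0.5 at prevalences 0.3/0.3: the mixture of the independence
    table with the comonotone Fréchet bound gives P(both)=0.195; validated by
    brute-force sampling at n=1e6."""
    joint = simulate.dual_bait_joint_table(0.3, 0.3, 0.5)
    expect = np.array([[0.595, 0.105], [0.105, 0.195]])
    np.testing.assert_allclose(joint, expect, atol=1e-12)

    cfg = simulate.DualBaitSimConfig(
        n_interactors=1_000_000, prevalence_a=0.3, prevalence_b=0.3,
        dependence=0.5, seed=31,
    )
    det, _ = simulate.generate_dual_bait_detections(cfg)
    a = det["bait_a"].to_numpy()
    b = det["bait_b"].to_numpy()
    n = len(det)
    emp = np.array(
        [[(~a & ~b).mean(), (~a & b).mean()], [(a & ~b).mean(), (a & b).mean()]]
    )
    tol = 4 * np.sqrt(expect * (1 - expect) / n)
    assert (np.abs(emp - expect) <= tol).all()
    # realized correlation equals the configured target
    assert abs(np.corrcoef(a, b)[0, 1] - 0.5) < 4 / np.sqrt(n)


def test_unachievable_dependence_reports_interval():
    # max correlation for prevalences 0.1/0.9 is (0.1 - 0.09)/0.09 = 0.111...
    with pytest.raises(ConfigError, match=r"achievable interval \[.*\]"):
        simulate.dual_bait_joint_table(0.1, 0.9, 0.9)
    with pytest.raises(ConfigError, match="dependence"):
        simulate.DualBaitSimConfig(prevalence_a=0.1, prevalence_b=0.9,
                                   dependence=0.9).validate()


def test_marginal_calibration_and_null_independence():
    n = 20_000
    cfg = simulate.DualBaitSimConfig(n_interactors=n, prevalence_a=0.35,
                                     prevalence_b=0.6, dependence=0.0, seed=4)
    det, _ = simulate.generate_dual_bait_detections(cfg)
    for col, p in (("bait_a", 0.35), ("bait_b", 0.6)):
        assert abs(det[col].mean() - p) < 4 * np.sqrt(p * (1 - p) / n)
    r = np.corrcoef(det["bait_a"], det["bait_b"])[0, 1]
    assert abs(r) < 4 / np.sqrt(n)


# ---------------------------------------------------------------------------
# PPI fixture


def _merge_fixture(paths):
    bg = read_biogrid_tab(paths["biogrid"])
    mt = read_mitab(paths["mitab"])
    omap = read_orthologs(paths["orthologs"])
    mapped_bg, _ = map_to_human(bg.records, omap)
    mapped_mt, _ = map_to_human(mt.records, omap)
    return merge(mapped_bg, mapped_mt)


def test_complete_chaperome_core(tmp_path):
    cfg = simulate.PpiSimConfig(n_nodes=10, n_chaperome=4, edge_prob_core=1.0,
                                ortholog_noise=0.0, seed=5)
    paths, truth = simulate.generate_ppi_fixture(cfg, tmp_path)
    core = sorted(truth.chaperome_ids)
    core_edges = {
        e for e in truth.merged_human_edges if e[0] in core and e[1] in core
    }
    assert len(core) == 4 and len(core_edges) == 6


def test_total_ortholog_noise_leaves_only_human_records(tmp_path):
    cfg = simulate.PpiSimConfig(n_nodes=40, ortholog_noise=1.0, seed=6)
    paths, truth = simulate.generate_ppi_fixture(cfg, tmp_path)
    db = _merge_fixture(paths)
    assert set(db.edges) == truth.merged_human_edges
    # every surviving edge must come from a native human record
    for (a, b) in db.edges:
        assert not a.startswith("t") and not b.startswith("t")


def test_merged_edge_recount_oracle(tmp_path):
    """Unique undirected edge count after merging the two dialects equals an
    independent set-based recount over the emitted files."""
    cfg = simulate.PpiSimConfig(n_nodes=50, ortholog_noise=0.2, seed=7)
    paths, truth = simulate.generate_ppi_fixture(cfg, tmp_path)

    # independent recount: raw text parsing, no package reader involved
    ortho = {}
    for line in paths["orthologs"].read_text().splitlines()[1:]:
        sid, taxid, hid = line.split("\t")
        ortho[(sid, int(taxid))] = hid

    def to_human(raw, taxon):
        return raw if taxon == 9606 else ortho.get((raw, taxon))

    recount = set()
    for line in paths["biogrid"].read_text().splitlines()[1:]:
        _, a, b, ta, tb = line.split("\t")
        ha, hb = to_human(a, int(ta)), to_human(b, int(tb))
        if ha and hb and ha != hb:
            recount.add(tuple(sorted((ha, hb))))
    for line in paths["mitab"].read_text().splitlines():
        f = line.split("\t")
        a, b = f[0].split(":", 1)[1], f[1].split(":", 1)[1]
        ta = int(f[9].split(":")[1].split("(")[0])
        tb = int(f[10].split(":")[1].split("(")[0])
        ha, hb = to_human(a, ta), to_human(b, tb)
        if ha and hb and ha != hb:
            recount.add(tuple(sorted((ha, hb))))

    db = _merge_fixture(paths)
    assert set(db.edges) == recount == truth.merged_human_edges


def test_fixture_determinism_byte_identical(tmp_path):
    cfg = simulate.PpiSimConfig(n_nodes=30, ortholog_noise=0.3, seed=8)
    p1, _ = simulate.generate_ppi_fixture(cfg, tmp_path / "x")
    p2, _ = simulate.generate_ppi_fixture(cfg, tmp_path / "y")
    for key in ("biogrid", "mitab", "orthologs", "chaperome", "gmt", "ground_truth"):
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_ground_truth_json_round_trip(tmp_path):
    cfg = simulate.PpiSimConfig(n_nodes=20, seed=9)
    paths, truth = simulate.generate_ppi_fixture(cfg, tmp_path)
    back = simulate.GroundTruth.from_json(paths["ground_truth"])
    assert back.chaperome_ids == truth.chaperome_ids
    assert back.merged_human_edges == truth.merged_human_edges
    assert back.planted_enriched_set == truth.planted_enriched_set
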