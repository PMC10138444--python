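"""Synthetic scenario generator: determinism, planted structure, recovery."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from cernapipe.gffio import read_fasta
from cernapipe.simulate import (
    ConfigurationError,
    GroundTruth,
    ScenarioConfig,
    evaluate_recovery,
    simulate_scenario,
)
from cernapipe.expression import read_counts
from cernapipe.lncrna import filter_noncoding


def _bundle_checksums(bundle: dict[str, Path]) -> dict[str, str]:
    return {name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in sorted(bundle.items())}


def test_same_seed_gives_byte_identical_bundles(tmp_path):
    cfg = ScenarioConfig(seed=42, n_mrna=20, n_lncrna=8, n_circrna=4,
                         n_mirna=6, n_triads=3)
    b1, _ = simulate_scenario(cfg, tmp_path / "a")
    b2, _ = simulate_scenario(cfg, tmp_path / "b")
    assert _bundle_checksums(b1) == _bundle_checksums(b2)


def test_count_matrix_dimensions(tmp_path):
    cfg = ScenarioConfig(seed=1, n_mrna=100, n_stages=4, n_reps=3,
                         n_lncrna=10, n_circrna=4, n_mirna=6, n_triads=2)
    bundle, _ = simulate_scenario(cfg, tmp_path)
    m = read_counts(bundle["counts_mrna.tsv"])
    assert m.values.shape == (100, 12)


def test_noise_free_triads_have_extreme_correlations(noise_free_scenario):
    """Monotone opposite stage means with zero noise force rank
    correlation -1 (miRNA vs target) and Pearson +1 (ceRNA vs mRNA)."""
    _, out, bundle, truth = noise_free_scenario
    mats = {
        "mrna": read_counts(bundle["counts_mrna.tsv"]),
        "lnc": read_counts(bundle["counts_lncrna.tsv"]),
        "circ": read_counts(bundle["counts_circrna.tsv"]),
        "mir": read_counts(bundle["counts_mirna.tsv"]),
    }

    def row(gid):
        key = {"mrna": "mrna", "lnc": "lnc", "circ": "circ", "mir": "mir"}[
            gid.split("_")[0]]
        return mats[key].row(gid)

    assert truth.planted_triads
    for cerna, mir, mrna in truth.planted_triads:
        rho1 = stats.spearmanr(row(mir), row(mrna)).statistic
        rho2 = stats.spearmanr(row(mir), row(cerna)).statistic
        r = stats.pearsonr(row(cerna), row(mrna)).statistic
        assert rho1 == pytest.approx(-1.0)
        assert rho2 == pytest.approx(-1.0)
        assert r == pytest.approx(1.0)


def test_planted_sites_are_reverse_complements(small_scenario):
    _, out, bundle, truth = small_scenario
    transcripts = read_fasta(bundle["transcripts.fa"])
    mirnas = read_fasta(bundle["mirnas.fa"])
    comp = str.maketrans("ACGT", "TGCA")
    for mir, target, pos in truth.planted_sites:
        site = transcripts[target][pos - 1: pos - 1 + len(mirnas[mir])]
        assert site == mirnas[mir].translate(comp)[::-1]


def test_planted_junction_flanks_are_canonical(small_scenario):
    """GT after the donor / AG before the acceptor on the planted strand
    (plus-strand letters CT/AC for minus-strand junctions)."""
    _, out, bundle, truth = small_scenario
    genome = read_fasta(bundle["genome.fa"])
    for chrom, acc, don, strand in truth.planted_junctions:
        seq = genome[chrom]
        before, after = seq[acc - 2:acc], seq[don + 1:don + 3]
        if strand == "+":
            assert (before, after) == ("AG", "GT")
        else:
            assert (before, after) == ("AC", "CT")


def test_planted_lncrnas_pass_noncoding_filter(small_scenario):
    _, out, bundle, truth = small_scenario
    transcripts = read_fasta(bundle["transcripts.fa"])
    lnc = {k: v for k, v in transcripts.items() if k.startswith("lnc_")}
    assert filter_noncoding(lnc) == set(lnc)


def test_nb_sampling_converges_to_planted_means(tmp_path):
    """With many replicates the per-stage sample mean approaches the
    planted mean (NB marginals are unbiased)."""
    cfg = ScenarioConfig(seed=9, n_reps=200, n_mrna=10, n_lncrna=2,
                         n_circrna=2, n_mirna=2, n_triads=1,
                         nb_dispersion=0.05, n_background_reads=10)
    bundle, _ = simulate_scenario(cfg, tmp_path)
    noisy = read_counts(bundle["counts_mrna.tsv"])
    import dataclasses
    cfg_nf = dataclasses.replace(cfg, noise_free=True)
    bundle_nf, _ = simulate_scenario(cfg_nf, tmp_path / "nf")
    exact = read_counts(bundle_nf["counts_mrna.tsv"])
    got = noisy.stage_means().to_numpy()
    want = exact.stage_means().to_numpy()
    assert np.all(np.abs(got - want) / want < 0.05)


def test_invalid_configs_rejected(tmp_path):
    with pytest.raises(ConfigurationError):
        ScenarioConfig(seed=0, n_stages=1)
    with pytest.raises(ConfigurationError):
        ScenarioConfig(seed=0, fold_change=1.0)
    with pytest.raises(ConfigurationError):
        ScenarioConfig(seed=0, n_triads=100, n_mirna=5)
    with pytest.raises(ConfigurationError):
        # genes cannot fit on the requested chromosome
        simulate_scenario(ScenarioConfig(seed=0, chrom_len=100), tmp_path)


@pytest.mark.parametrize(
    "predicted, expected",
    [
        ("all", (1.0, 1.0, False)),
        ("none", (0.0, 0.0, True)),
        ("half", (1.0, 0.5, False)),
    ],
)
def test_evaluate_recovery_conventions(predicted, expected):
    truth = GroundTruth(
        planted_triads=[(f"c{i}", f"m{i}", f"g{i}") for i in range(10)],
        planted_de={}, planted_sites=[], planted_junctions=[],
        enriched_terms=[])
    pred = {"all": truth.planted_triads,
            "none": [],
            "half": truth.planted_triads[:5]}[predicted]
    rep = evaluate_recovery(pred, truth)
    precision, recall, undefined = expected
    assert rep.precision == precision
    assert rep.recall == recall
    assert rep.precision_undefined is undefined
    assert rep.hit_table.shape[0] == 10
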