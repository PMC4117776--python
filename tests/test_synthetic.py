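"""The simulator plants recoverable truth and is reproducible from its seed."""

import math

import pytest

import polyhist as ph
from polyhist.alignio import HDE_CONSENSUS


def test_fixed_seed_reproduces_everything_byte_identically():
    cfg = ph.SimConfig(n_genes=2, contig_length=2500, depth_per_condition=200,
                       seed=1)
    out = []
    for _ in range(2):
        genome, models, truth = ph.make_toy_genome(cfg)
        reads, sidecar = ph.simulate_aseq_reads(genome, models, truth, "wt", cfg)
        ct = ph.simulate_ct_table(truth, noise_sd=0.3, seed=cfg.seed)
        out.append((genome, [m.__dict__ for m in models], truth.to_frame(),
                    [(r.read_id, r.sequence) for r in reads],
                    [(c.sample_id, c.target_gene, c.priming, c.ct_values)
                     for c in ct]))
    assert out[0][0] == out[1][0]
    assert out[0][1] == out[1][1]
    assert out[0][2].equals(out[1][2])
    assert out[0][3] == out[1][3]
    assert out[0][4] == out[1][4]


def test_single_gene_has_exactly_one_hde_downstream_of_cleavage():
    cfg = ph.SimConfig(n_genes=1, contig_length=1500, depth_per_condition=50,
                       seed=3)
    genome, models, truth = ph.make_toy_genome(cfg)
    m = models[0]
    region = genome[m.contig][m.canonical_cleavage:m.transcript[1]]
    assert region.count(HDE_CONSENSUS) == 1
    assert m.hde[0] >= m.canonical_cleavage


def test_impossible_placement_raises_sizing_error():
    with pytest.raises(ph.SizingError):
        ph.make_toy_genome(ph.SimConfig(n_genes=50, contig_length=1000,
                                        depth_per_condition=10, seed=0))


@pytest.mark.parametrize("bad", [
    dict(tail_length_range=(0, 5)),
    dict(error_rate=1.0),
    dict(polyA_fraction=0.5, effect_size=3.0),
    dict(read_length=0),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        ph.SimConfig(**bad)


def test_gene_layout_geometry(small_sim):
    genome, models, _ = small_sim
    for m in models:
        sl_gap = m.canonical_cleavage - m.stem_loop[1]
        hde_gap = m.hde[0] - m.canonical_cleavage
        assert 4 <= sl_gap <= 6
        assert 9 <= hde_gap <= 13
        assert m.stem_loop[1] - m.stem_loop[0] == 16
        assert genome[m.contig][m.hde[0]:m.hde[1]] == HDE_CONSENSUS
        assert genome[m.contig][m.canonical_cleavage] != "A"


def test_read_counts_hit_depth_exactly_and_reads_are_read_length(small_config,
                                                                 small_sim):
    genome, models, truth = small_sim
    for cond in small_config.conditions:
        assert sum(t.reads[cond] for t in truth.genes.values()) == \
            small_config.depth_per_condition
        reads, sidecar = ph.simulate_aseq_reads(genome, models, truth, cond,
                                                small_config)
        assert len(reads) == small_config.depth_per_condition
        assert all(len(r.sequence) == small_config.read_length for r in reads)


def test_tailed_reads_end_in_untemplated_adenosines(small_config, small_sim):
    """Error-free polyadenylated reads end at the cleavage coordinate in >=1
    A that the genome does not template."""
    genome, models, truth = small_sim
    contig = genome[small_config.contig_name]
    reads, _ = ph.simulate_aseq_reads(genome, models, truth, "wt", small_config)
    tailed = [r for r in reads if r.polyadenylated]
    assert tailed
    for r in tailed:
        k = r.tail_length
        assert k >= 1
        assert r.sequence[-k:] == "A" * k
        assert r.sequence[:-k] == contig[r.site - (len(r.sequence) - k):r.site]
        assert contig[r.site] != "A"


def test_tailed_read_count_is_binomial():
    cfg = ph.SimConfig(n_genes=5, contig_length=5000, depth_per_condition=1000,
                       polyA_fraction=0.1, effect_size=1.0, duplicate_rate=0.0,
                       seed=5)
    genome, models, truth = ph.make_toy_genome(cfg)
    _, sidecar = ph.simulate_aseq_reads(genome, models, truth, "wt", cfg)
    n_tailed = int(sidecar.polyadenylated.sum())
    assert abs(n_tailed - 100) <= 3 * math.sqrt(1000 * 0.1 * 0.9)


def test_unit_effect_size_gives_matched_conditions():
    cfg = ph.SimConfig(n_genes=5, contig_length=5000,
                       depth_per_condition=10_000, polyA_fraction=0.1,
                       effect_size=1.0, duplicate_rate=0.0, seed=13)
    genome, models, truth = ph.make_toy_genome(cfg)
    fracs = {}
    for cond in cfg.conditions:
        _, sidecar = ph.simulate_aseq_reads(genome, models, truth, cond, cfg)
        fracs[cond] = sidecar.polyadenylated.mean()
    se = math.sqrt(2 * 0.1 * 0.9 / 10_000)
    assert abs(fracs["wt"] - fracs["ko"]) <= 3 * se


def test_duplicates_are_byte_identical_copies():
    cfg = ph.SimConfig(n_genes=2, contig_length=2500, depth_per_condition=500,
                       duplicate_rate=0.5, error_rate=0.01, seed=2)
    genome, models, truth = ph.make_toy_genome(cfg)
    reads, sidecar = ph.simulate_aseq_reads(genome, models, truth, "wt", cfg)
    by_id = {r.read_id: r for r in reads}
    dups = sidecar[sidecar.duplicate_of != "."]
    assert len(dups) > 100
    for row in dups.itertuples():
        assert by_id[row.read_id].sequence == by_id[row.duplicate_of].sequence


def test_ct_simulation_closed_forms(small_sim):
    """Noise-free Ct differences follow -log2(quantity ratio)/log2(1+E)."""
    _, _, truth = small_sim
    ct = ph.simulate_ct_table(truth, amplification_efficiency=1.0,
                              noise_sd=0.0, seed=1)
    def mean_ct(sample, gene, priming):
        for r in ct:
            if (r.sample_id, r.target_gene, r.priming) == (sample, gene, priming):
                return sum(r.ct_values) / len(r.ct_values)
        raise KeyError
    gene = next(iter(truth.genes))
    ratio = truth.genes[gene].polya["ko"] / truth.genes[gene].polya["wt"]
    dct = mean_ct("ko", gene, "oligo_dT") - mean_ct("wt", gene, "oligo_dT")
    assert dct == pytest.approx(-math.log2(ratio), abs=1e-12)
    # total (random-primed) and reference quantities are condition-invariant
    assert mean_ct("ko", gene, "random") == pytest.approx(
        mean_ct("wt", gene, "random"), abs=1e-12)
    assert mean_ct("ko", "Rps2", "oligo_dT") == pytest.approx(
        mean_ct("wt", "Rps2", "oligo_dT"), abs=1e-12)
    # -RT rows model clean controls
    for r in ct:
        if r.priming == "minus_RT":
            assert ph.check_minus_rt(r) == "pass"


def test_ct_simulation_rejects_bad_efficiency(small_sim):
    _, _, truth = small_sim
    with pytest.raises(ValueError):
        ph.simulate_ct_table(truth, amplification_efficiency=0.0)


def test_write_simulation_round_trips(tmp_path, small_config):
    import pandas as pd
    ph.write_simulation(small_config, tmp_path)
    genome = ph.read_fasta(tmp_path / "genome.fa")
    models_bed = ph.parse_gene_models(tmp_path / "genes.bed", format="bed")
    models_gff = ph.parse_gene_models(tmp_path / "genes.gff3", format="gff3")
    assert models_bed == models_gff
    assert len(models_bed) == small_config.n_genes
    for cond in small_config.conditions:
        reads = ph.read_fastq(tmp_path / f"reads_{cond}.fastq")
        assert len(reads) == small_config.depth_per_condition
        sidecar = pd.read_csv(tmp_path / f"truth_reads_{cond}.tsv", sep="\t")
        assert list(sidecar.read_id) == [rid for rid, _ in reads]
    ct = ph.read_ct_table(tmp_path / "ct_table.tsv")
    assert any(r.is_reference for r in ct)
    assert len(genome[small_config.contig_name]) == small_config.contig_length
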