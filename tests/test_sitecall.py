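"""Read collapsing, the cleavage-site rule and site aggregation."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

import polyhist as ph
from polyhist.alignio import AlignedRead
from polyhist.sitecall import ReadSiteCall


# ---------------------------------------------------------------------------
# collapse_identical
# ---------------------------------------------------------------------------

def test_collapse_counts_and_preserves_first_occurrence_order():
    assert ph.collapse_identical(["AAC", "AAC", "AGT"]) == [("AAC", 2), ("AGT", 1)]
    assert ph.collapse_identical([]) == []


def test_collapse_is_idempotent_on_representatives():
    reps = [s for s, _ in ph.collapse_identical(["T", "G", "T", "T", "G", "C"])]
    assert ph.collapse_identical(reps) == [(s, 1) for s in reps]


@given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=8), max_size=60))
def test_collapse_conserves_multiplicity_totals(seqs):
    collapsed = ph.collapse_identical(seqs)
    assert sum(m for _, m in collapsed) == len(seqs)
    assert len({s for s, _ in collapsed}) == len(collapsed)


# ---------------------------------------------------------------------------
# call_cleavage_site: the genomic-A disambiguation rule
# ---------------------------------------------------------------------------

def aligned(tail, start=10, span=20, **kw):
    return AlignedRead(read_id="r", contig="c", strand="+", start=start,
                       aligned_span=span, tail=tail, **kw)


def genome_with(context):
    """20 non-A bases, then the junction context under test."""
    return {"c": "CGTCGTCGTCGTCGTCGTCG" + context + "CGT"}


def test_non_a_junction_places_site_at_alignment_end():
    g = genome_with("TCCG")
    call = ph.call_cleavage_site(aligned("AAAA", start=0), g)
    assert call.site == 20
    assert call.tail == "AAAA"


def test_single_genomic_a_shifts_site_by_one():
    g = genome_with("AGGC")
    call = ph.call_cleavage_site(aligned("AAAA", start=0), g)
    assert call.site == 21
    assert call.tail == "AAA"


def test_genomic_a_run_shifts_site_past_the_run():
    g = genome_with("AATG")
    call = ph.call_cleavage_site(aligned("AAAA", start=0), g)
    assert call.site == 22
    assert call.tail == "AA"


def test_single_mode_shifts_by_at_most_one_a():
    g = genome_with("AATG")
    call = ph.call_cleavage_site(aligned("AAAA", start=0), g, a_run="single")
    assert call.site == 21
    assert call.tail == "AAA"


def test_fully_templatable_tail_is_no_call():
    g = genome_with("AAAAAA")
    assert ph.call_cleavage_site(aligned("AAAA", start=0), g) is None


def test_empty_tail_and_multimapped_and_artifact_tails_are_no_calls():
    g = genome_with("TCCG")
    assert ph.call_cleavage_site(aligned("", start=0), g) is None
    assert ph.call_cleavage_site(aligned("AAAA", start=0, multimapped=True),
                                 g) is None
    # half the untemplated suffix is non-A: suspected artifact
    assert ph.call_cleavage_site(aligned("ACGA", start=0), g) is None
    # ... unless the filter is disabled
    assert ph.call_cleavage_site(aligned("ACGA", start=0), g,
                                 tail_a_frac_min=0.0) is not None


def oracle_site(context, tail, e=0):
    """Maximal templated-prefix split of the tail against the genome.

    A fully templated tail leaves no untemplated evidence: no-call (None).
    """
    best = max(j for j in range(len(tail) + 1) if tail[:j] == context[:j])
    return None if best == len(tail) else e + best


@pytest.mark.parametrize("ctx_len,tail_len", [(3, 1), (3, 2), (3, 3)])
def test_a_run_rule_matches_split_oracle_on_small_contexts(ctx_len, tail_len):
    for ctx in map("".join, itertools.product("ACGT", repeat=ctx_len)):
        g = genome_with(ctx)
        tail = "A" * tail_len
        call = ph.call_cleavage_site(aligned(tail, start=0), g,
                                     tail_a_frac_min=0.0)
        expect = oracle_site(ctx, tail, e=20)
        if expect is None:
            assert call is None
        else:
            assert call.site == expect


# ---------------------------------------------------------------------------
# site table construction and gene assignment
# ---------------------------------------------------------------------------

def test_build_site_table_merges_sites_and_sums_multiplicities():
    calls = [ReadSiteCall("c", "+", 100, "AAA", multiplicity=3),
             ReadSiteCall("c", "+", 100, "AAAA", multiplicity=2),
             ReadSiteCall("c", "+", 250, "AA", multiplicity=1)]
    table = ph.build_site_table(calls)
    assert [s.site for s in table.sites] == [100, 250]
    first = table.sites[0]
    assert first.raw_count == 5
    assert first.collapsed_count == 2
    assert first.mean_tail_length == pytest.approx((3 * 3 + 4 * 2) / 5)
    assert first.tail_A_fraction == 1.0


def test_build_site_table_empty_input():
    assert ph.build_site_table([]).sites == []


@pytest.fixture()
def one_gene_model():
    return ph.GeneModel(gene_id="g", contig="c", strand="+",
                        transcript=(0, 300), utr3=(100, 300),
                        stem_loop=(150, 166), hde=(181, 191),
                        canonical_cleavage=172)


def site_at(pos, n=1):
    return ReadSiteCall("c", "+", pos, "AAA", multiplicity=n)


def test_site_labels_against_canonical_cleavage(one_gene_model):
    table = ph.build_site_table(
        [site_at(172), site_at(174), site_at(672), site_at(120), site_at(5000)])
    ph.assign_sites_to_genes(table, [one_gene_model])
    labels = {s.site: s.label for s in table.sites}
    assert labels[172] == "stem_loop_site"
    assert labels[174] == "stem_loop_site"  # within the +-2 nt tolerance
    assert labels[672] == "downstream"      # canonical + 500, inside window
    assert labels[120] == "other"           # upstream of the stem-loop
    assert labels[5000] == "intergenic"
    g = table.genes["g"]
    assert g.raw_total == 4  # the intergenic site is excluded


def test_gene_totals_equal_sum_of_member_sites(fixture_site_tables, fixture_sim):
    tables, _ = fixture_site_tables
    for table in tables.values():
        per_gene = {}
        for s in table.sites:
            if s.gene_id is not None:
                per_gene[s.gene_id] = per_gene.get(s.gene_id, 0) + s.raw_count
        for gid, summary in table.genes.items():
            assert summary.raw_total == per_gene.get(gid, 0)


def test_count_conservation_raw_counts_equal_calling_reads(fixture_site_tables):
    tables, stats = fixture_site_tables
    for cond, table in tables.items():
        assert sum(s.raw_count for s in table.sites) == stats[cond].n_called
        for s in table.sites:
            assert s.collapsed_count <= s.raw_count


def test_writers_and_parsers_round_trip(tmp_path, fixture_site_tables):
    tables, _ = fixture_site_tables
    table = tables["ko"]
    table.write_bed(tmp_path / "s.bed")
    table.write_bedgraph(tmp_path / "s.bedgraph")
    table.write_tsv(tmp_path / "s.tsv")
    bed = ph.SiteTable.read_bed(tmp_path / "s.bed")
    assert [(r[0], r[1], r[4], r[5]) for r in bed] == \
        [(s.contig, s.site, s.raw_count, s.strand) for s in table.sites]
    bg = ph.SiteTable.read_bedgraph(tmp_path / "s.bedgraph")
    assert [(r[1], r[3]) for r in bg] == \
        [(s.site, s.raw_count) for s in table.sites]
    df = ph.SiteTable.read_tsv(tmp_path / "s.tsv")
    assert list(df.site) == [s.site for s in table.sites]
    assert list(df.collapsed_count) == [s.collapsed_count for s in table.sites]
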