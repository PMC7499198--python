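import numpy as np
import pytest

from svburden import (GenomeIndex, SVRecord, build_carrier_matrix,
                      classify_all, classify_sv, load_annotation, merge_loci,
                      simulate_annotation)
from svburden.classify import ManifestMismatch, SVGeneAssignment
from svburden.simulate import SimulationConfig

from .conftest import make_aa_ea_manifest
from .oracles import brute_classify


def _sv(sv_type, chrom, start, end, length=None, sample="s1", id="x"):
    if length is None:
        length = end - start if sv_type not in ("INS", "BND") else 0
    return SVRecord(sample, sv_type, chrom, start, end, length, "PASS", id=id)


def _classes(assignments):
    return sorted((a.region_class, a.gene_id, a.distance) for a in assignments)


# gene A (0-based): span [1000,2000), exons [1000,1200) and [1800,2000),
# intron [1200,1800); overlapping gene C span [1050,1950)

def test_deletion_inside_intron_is_intronic(toy_index):
    got = _classes(classify_sv(_sv("DEL", "chr1", 1250, 1700), toy_index))
    assert ("intronic", "A", 0) in got


def test_deletion_across_exon_intron_border_is_splicing(toy_index):
    got = _classes(classify_sv(_sv("DEL", "chr1", 1100, 1500), toy_index))
    assert ("splicing", "A", 0) in got
    assert not any(c == "exonic" and g == "A" for c, g, _ in got)


def test_insertion_point_in_exon_is_exonic(toy_index):
    got = _classes(classify_sv(_sv("INS", "chr1", 1100, 1101, 120), toy_index))
    assert ("exonic", "A", 0) in got


def test_intergenic_deletion_assigned_to_nearest_gene(toy_index):
    # midpoint 2449 is 450 bp right of A's last base, 550 left of B
    got = _classes(classify_sv(_sv("DEL", "chr1", 2399, 2499), toy_index))
    assert got == [("intergenic", "A", 450)]


def test_deletion_spanning_two_exons_is_exonic_and_splicing(toy_index):
    # both breakpoints in exons of A, span crosses the intron
    got = [x for x in _classes(classify_sv(_sv("DEL", "chr1", 1100, 1900),
                                           toy_index)) if x[1] == "A"]
    assert got == [("exonic", "A", 0), ("splicing", "A", 0)]


def test_sv_containing_whole_gene_is_splicing_for_it(toy_index):
    # breakpoints intergenic on both sides of gene B
    got = _classes(classify_sv(_sv("DEL", "chr1", 2500, 4500), toy_index))
    assert ("splicing", "B", 0) in got


def test_bnd_breakends_classified_as_points(toy_index):
    assert _classes(classify_sv(_sv("BND", "chr1", 1100, 1101), toy_index)) \
        == [("exonic", "A", 0)]
    got = _classes(classify_sv(_sv("BND", "chr1", 1500, 1501), toy_index))
    assert ("intronic", "A", 0) in got and ("intronic", "C", 0) in got


def test_every_sv_gets_an_assignment_and_legal_class_set(toy_index):
    rng = np.random.default_rng(3)
    for _ in range(200):
        start = int(rng.integers(0, 5000))
        length = int(rng.integers(50, 1200))
        sv = _sv("DEL", "chr1", start, start + length)
        assigns = classify_sv(sv, toy_index)
        assert assigns
        per_gene = {}
        for a in assigns:
            per_gene.setdefault(a.gene_id, set()).add(a.region_class)
        for classes in per_gene.values():
            assert classes in ({"exonic"}, {"intronic"}, {"splicing"},
                               {"exonic", "splicing"}, {"intergenic"})
        if any(a.region_class == "intergenic" for a in assigns):
            assert len(assigns) == 1


@pytest.fixture(scope="module")
def fuzz_setup():
    cfg = SimulationConfig(seed=29, n_genes=30, n_chroms=2,
                           intergenic_len=(500, 3000))
    genes = load_annotation(simulate_annotation(cfg).splitlines())
    return genes, GenomeIndex(genes)


def test_fuzzed_svs_match_brute_force_classifier(fuzz_setup):
    genes, index = fuzz_setup
    rng = np.random.default_rng(31)
    hi = max(g.span[1] for g in genes) + 3000
    agree = 0
    for i in range(500):
        sv_type = ["DEL", "DUP", "INV", "INS", "BND"][int(rng.integers(5))]
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(0, hi))
        if sv_type in ("INS", "BND"):
            sv = _sv(sv_type, chrom, start, start + 1, id=f"f{i}")
        else:
            length = int(rng.integers(50, 5000))
            sv = _sv(sv_type, chrom, start, start + length, id=f"f{i}")
        expected = sorted(brute_classify(genes, sv))
        got = _classes(classify_sv(sv, index))
        assert got == expected, f"SV {sv} -> {got} != {expected}"
        agree += 1
    assert agree == 500


def test_identical_deletions_merge_into_one_cluster(toy_index):
    svs = [_sv("DEL", "chr5", 171723712, 171724032, sample=f"s{i}", id=f"d{i}")
           for i in range(3)]
    assigns = [SVGeneAssignment(sv, "intronic", "A") for sv in svs]
    (cluster,) = merge_loci(assigns)
    assert cluster.occurrence == 3
    assert cluster.carriers == {"s0", "s1", "s2"}
    assert (cluster.start, cluster.end) == (171723712, 171724032)


def test_deletions_offset_beyond_window_stay_separate():
    a = _sv("DEL", "chr1", 1000, 1500, sample="s1", id="a")
    b = _sv("DEL", "chr1", 1200, 1700, sample="s2", id="b")
    assigns = [SVGeneAssignment(a, "intronic", "G"),
               SVGeneAssignment(b, "intronic", "G")]
    assert len(merge_loci(assigns)) == 2


def test_breakpoint_window_and_reciprocal_overlap_both_required():
    a = _sv("DEL", "chr1", 1000, 1060, sample="s1", id="a")
    b = _sv("DEL", "chr1", 1030, 1090, sample="s2", id="b")   # 50% overlap
    assigns = [SVGeneAssignment(a, "intronic", "G"),
               SVGeneAssignment(b, "intronic", "G")]
    assert len(merge_loci(assigns)) == 2
    assert len(merge_loci(assigns, reciprocal_overlap=0.4)) == 1


def test_merge_is_input_order_invariant_and_idempotent():
    rng = np.random.default_rng(37)
    svs = []
    for i in range(60):
        start = int(rng.integers(0, 2000))
        svs.append(_sv("DEL", "chr1", start, start + int(rng.integers(100, 400)),
                       sample=f"s{i % 10}", id=f"r{i}"))
    assigns = [SVGeneAssignment(sv, "intronic", "G") for sv in svs]

    def snapshot(clusters):
        return [(c.chrom, c.start, c.end, c.sv_type, tuple(sorted(c.carriers)))
                for c in clusters]

    ref = snapshot(merge_loci(assigns))
    perm = [assigns[i] for i in rng.permutation(len(assigns))]
    assert snapshot(merge_loci(perm)) == ref
    total_carrier_links = sum(len(c[4]) for c in ref)
    assert total_carrier_links <= len({(a.sv.sample_id, a.sv.event_key)
                                       for a in assigns})


def test_carrier_collapse_multiple_events_count_once(small_manifest):
    svs = [_sv("DEL", "chr1", 1250 + i * 10, 1300 + i * 10, sample="s1",
               id=f"d{i}") for i in range(3)]
    assigns = [SVGeneAssignment(sv, "intronic", "X") for sv in svs]
    mat = build_carrier_matrix(assigns, small_manifest)
    assert mat.shape[0] == 1
    assert mat.loc[("X", "intronic", "DEL")].sum() == 1


def test_carrier_matrix_counts_match_known_carrier_layout():
    # 9 of 116 cases and 7 of 408 controls carry an exonic insertion
    manifest = make_aa_ea_manifest()
    cases = manifest.stratum_samples("AA", "case")[:9]
    ctrls = manifest.stratum_samples("AA", "control")[:7]
    assigns = [
        SVGeneAssignment(_sv("INS", "chr1", 1100, 1101, 100, sample=s,
                             id=f"i{k}"), "exonic", "GX")
        for k, s in enumerate(cases + ctrls)]
    mat = build_carrier_matrix(assigns, manifest)
    row = mat.loc[("GX", "exonic", "INS")]
    assert row[manifest.stratum_samples("AA", "case")].sum() == 9
    assert row[manifest.stratum_samples("AA", "control")].sum() == 7
    assert row.sum() == 16


def test_locus_mode_row_sums_equal_cluster_carrier_sets(small_manifest):
    svs = [_sv("DEL", "chr1", 1000, 1300, sample=s, id=f"d{s}")
           for s in ("s1", "s2", "s4")]
    svs.append(_sv("DEL", "chr1", 5000, 5400, sample="s2", id="far"))
    assigns = [SVGeneAssignment(sv, "intronic", "G") for sv in svs]
    clusters = merge_loci(assigns)
    mat = build_carrier_matrix(assigns, small_manifest, unit="locus",
                               clusters=clusters)
    for c in clusters:
        assert mat.loc[c.cluster_id].sum() == len(c.carriers)


def test_strict_mode_rejects_unknown_samples(small_manifest):
    assigns = [SVGeneAssignment(_sv("DEL", "chr1", 1250, 1400,
                                    sample="ghost"), "intronic", "X")]
    with pytest.raises(ManifestMismatch):
        build_carrier_matrix(assigns, small_manifest, strict=True)
    mat = build_carrier_matrix(assigns, small_manifest, strict=False)
    assert mat.shape[0] == 0
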