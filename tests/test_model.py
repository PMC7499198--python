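import io

import numpy as np
import pandas as pd
import pytest

from svburden import (SVBurdenModel, SVRecord, carrier_table,
                      ethnicity_overlap, geneset_tally, read_gmt,
                      rare_recurrent_filter)
from svburden.classify import SVGeneAssignment, SVLocusCluster

from .conftest import make_aa_ea_manifest


def _matrix(keys, carriers_by_key, samples):
    mat = pd.DataFrame(False, index=pd.MultiIndex.from_tuples(
        keys, names=["gene_id", "region_class", "sv_type"]),
        columns=sorted(samples), dtype=bool)
    for key, carriers in carriers_by_key.items():
        mat.loc[key, sorted(carriers)] = True
    return mat


def test_carrier_table_toy(small_manifest):
    mat = _matrix([("X", "intronic", "DEL")],
                  {("X", "intronic", "DEL"): ["s1", "s2"]},
                  small_manifest.samples)
    t = carrier_table(mat, ("X", "intronic", "DEL"), small_manifest, "AA")
    assert (t.a, t.b, t.c, t.d) == (2, 1, 0, 3)


def test_carrier_table_known_cohort_sizes():
    # 9 case and 7 control carriers at AA stratum sizes 116/408
    manifest = make_aa_ea_manifest()
    key = ("GX", "exonic", "INS")
    carriers = (manifest.stratum_samples("AA", "case")[:9]
                + manifest.stratum_samples("AA", "control")[:7])
    mat = _matrix([key], {key: carriers}, manifest.samples)
    t = carrier_table(mat, key, manifest, "AA")
    assert (t.a, t.b, t.c, t.d) == (9, 107, 7, 401)


def test_margins_equal_manifest_totals_for_every_key(small_manifest):
    rng = np.random.default_rng(2)
    keys = [(f"G{i}", "intronic", "DEL") for i in range(6)]
    samples = sorted(small_manifest.samples)
    carr = {k: [s for s in samples if rng.random() < 0.5] for k in keys}
    mat = _matrix(keys, carr, samples)
    for k in keys:
        t = carrier_table(mat, k, small_manifest, "AA")
        assert t.a + t.b == 3 and t.c + t.d == 3


def _fit_two_strata():
    manifest = make_aa_ea_manifest(10, 20, 8, 16)
    keys = [("G1", "intronic", "DEL"), ("G2", "exonic", "INS"),
            ("G3", "intronic", "DEL")]
    aa_cases = manifest.stratum_samples("AA", "case")
    aa_ctrls = manifest.stratum_samples("AA", "control")
    ea_cases = manifest.stratum_samples("EA", "case")
    ea_ctrls = manifest.stratum_samples("EA", "control")
    carr = {
        keys[0]: aa_cases[:6] + aa_ctrls[:2] + ea_cases[:5] + ea_ctrls[:2],
        keys[1]: aa_cases[:1] + aa_ctrls[:8] + ea_cases[:1] + ea_ctrls[:6],
        keys[2]: aa_cases[:3] + aa_ctrls[:6] + ea_cases[:2] + ea_ctrls[:4],
    }
    mat = _matrix(keys, carr, manifest.samples)
    return SVBurdenModel(mat, manifest).fit(), keys


def test_results_sorted_by_chi2_p_with_adjusted_bounds():
    res, _ = _fit_two_strata()
    for s in ("AA", "EA"):
        df = res.frame(s)
        assert list(df["chi2_p"]) == sorted(df["chi2_p"])
        assert (df["chi2_p_adj"] >= df["chi2_p"] - 1e-15).all()
        assert (df["chi2_p_adj"] <= 1.0).all()
        assert (df["fisher_p_adj"] >= df["fisher_p"] - 1e-15).all()


def test_risk_only_excludes_protective_keys_from_significant_set():
    res, keys = _fit_two_strata()
    aa = res.frame("AA").set_index("key")
    protective = aa.loc[[keys[1]]]
    assert (protective["odds_ratio"] < 1).all()
    assert not protective["significant"].any()
    assert keys[1] not in set(res.significant("AA")["key"])


def test_meta_combines_across_strata_and_orders_by_p():
    res, keys = _fit_two_strata()
    assert res.meta is not None
    m = dict(zip(res.meta["key"], res.meta["meta_p"]))
    assert set(m) == set(keys)
    assert (res.meta["k"] == 2).all()
    aa = dict(zip(res.frame("AA")["key"], res.frame("AA")["chi2_p"]))
    ea = dict(zip(res.frame("EA")["key"], res.frame("EA")["chi2_p"]))
    for k in keys:
        from svburden import meta_combine
        expect = meta_combine([aa[k], ea[k]]).p
        assert m[k] == pytest.approx(expect)
    assert list(res.meta["meta_p"]) == sorted(res.meta["meta_p"])


def test_summary_reports_cohort_and_top_keys():
    res, _ = _fit_two_strata()
    text = res.summary()
    assert "stratum AA: 10 cases / 20 controls" in text
    assert "OR=" in text and "meta-analysis" in text


def _cluster(case_ids, ctrl_ids, cid="c1"):
    return SVLocusCluster(cid, "DEL", "chr1", 100, 500,
                          carriers=set(case_ids) | set(ctrl_ids))


def test_rare_recurrent_keeps_case_only_recurrent_loci():
    manifest = make_aa_ea_manifest(10, 400, 8, 16)
    cases = manifest.stratum_samples("AA", "case")
    ctrls = manifest.stratum_samples("AA", "control")
    keep = _cluster(cases[:3], [], "k")          # 3 cases, 0 controls
    drop_single = _cluster(cases[:1], [], "s")   # only 1 case
    out = rare_recurrent_filter([keep, drop_single], manifest,
                                case_only=True)
    assert [c.cluster_id for c in out] == ["k"]


def test_rare_recurrent_control_frequency_boundary():
    # 416 controls in total; 3 control carriers = 0.72% > 0.5% -> dropped,
    # 2 control carriers = 0.48% < 0.5% -> kept
    manifest = make_aa_ea_manifest(10, 400, 8, 16)
    cases = manifest.stratum_samples("AA", "case")
    ctrls = manifest.stratum_samples("AA", "control")
    dropped = _cluster(cases[:2], ctrls[:3], "hi")
    kept = _cluster(cases[:2], ctrls[:2], "lo")
    out = rare_recurrent_filter([dropped, kept], manifest, case_only=False)
    assert [c.cluster_id for c in out] == ["lo"]


def test_overlap_identical_and_disjoint_sets():
    same = {"AA": {"all": set("ABCDEFGHIJ")}, "EA": {"all": set("ABCDEFGHIJ")}}
    out = ethnicity_overlap(same)
    assert len(out["all"]["intersection"]) == 10
    assert out["all"]["overlap_fraction"] == {"AA": 1.0, "EA": 1.0}
    disjoint = {"AA": {"all": {"A", "B", "C"}}, "EA": {"all": {"X", "Y", "Z", "W"}}}
    out = ethnicity_overlap(disjoint)
    assert out["all"]["intersection"] == []
    assert out["all"]["jaccard"] == 0.0


def test_overlap_matches_direct_set_algebra_on_fuzzed_sets():
    rng = np.random.default_rng(43)
    genes = [f"G{i}" for i in range(50)]
    for _ in range(20):
        aa = {g for g in genes if rng.random() < 0.3}
        ea = {g for g in genes if rng.random() < 0.3}
        if not aa or not ea:
            continue
        out = ethnicity_overlap({"AA": {"all": aa}, "EA": {"all": ea}})["all"]
        assert set(out["intersection"]) == aa & ea
        assert set(out["exclusive"]["AA"]) == aa - ea
        assert set(out["exclusive"]["EA"]) == ea - aa
        assert out["overlap_fraction"]["AA"] == len(aa & ea) / len(aa)


def test_overlap_restricted_to_known_genes():
    out = ethnicity_overlap({"AA": {"all": {"A", "B", "K"}},
                             "EA": {"all": {"B", "K", "Z"}}},
                            known_genes={"K", "Z"})
    assert out["all"]["per_stratum"] == {"AA": ["K"], "EA": ["K", "Z"]}
    assert out["all"]["intersection"] == ["K"]


def test_read_gmt_and_tally():
    gmt = ("pathway1\tdesc\tX\tY\n"
           "pathway2\tdesc\tY\tZ\n"
           "empty\tdesc\n")
    sets = read_gmt(io.StringIO(gmt))
    assert sets == {"pathway1": ["X", "Y"], "pathway2": ["Y", "Z"]}
    frames = {"AA": pd.DataFrame({
        "key": [("X", "intronic", "DEL"), ("Y", "exonic", "INS"),
                ("Q", "intronic", "DEL")],
        "odds_ratio": [2.5, 1.9, 3.0],
        "chi2_p": [0.01, 0.08, 0.5]})}
    tally = geneset_tally(frames, sets, alpha=0.05, trend_alpha=0.1)
    assert set(map(tuple, tally[["gene_set", "gene_id", "tier"]].values)) == {
        ("pathway1", "X", "significant"), ("pathway1", "Y", "trend"),
        ("pathway2", "Y", "trend")}
    # gene Y sits in both sets and appears in both rows; Q (no set) and the
    # p=0.5 key are absent
    assert (tally["gene_id"] != "Q").all()
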