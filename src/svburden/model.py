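"""Case-control SV burden model and results.

`SVBurdenModel` wraps a binary carrier matrix plus a cohort manifest and,
on `fit()`, produces per-stratum carrier 2x2 tables, odds ratios with Woolf
confidence intervals, chi-square and Fisher exact p-values, Bonferroni
adjustment, and a Fisher's combined-probability meta-analysis across
strata.  `SVBurdenResults` carries those tables and the downstream
summaries: significant-set extraction, cross-stratum overlap, rare
recurrent case-only loci and gene-set membership tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .classify import SVLocusCluster, build_carrier_matrix
from .sv_io import CohortManifest
from . import stats as st

logger = logging.getLogger(__name__)

__all__ = [
    "SVBurdenModel",
    "SVBurdenResults",
    "carrier_table",
    "rare_recurrent_filter",
    "ethnicity_overlap",
    "geneset_tally",
    "read_gmt",
]

_KEY_COLS = ["gene_id", "region_class", "sv_type"]


def carrier_table(matrix: pd.DataFrame, key, manifest: CohortManifest,
                  stratum: str) -> st.ContingencyTable:
    """Carrier 2x2 for one matrix key within one stratum."""
    cases = manifest.stratum_samples(stratum, "case")
    controls = manifest.stratum_samples(stratum, "control")
    if not cases and not controls:
        raise ValueError(f"stratum {stratum!r} is empty")
    row = matrix.loc[key]
    a = int(row[cases].sum())
    c = int(row[controls].sum())
    return st.ContingencyTable(a, len(cases) - a, c, len(controls) - c)


class SVBurdenModel:
    """Carrier burden association model over (gene, class, type) keys.

    Parameters
    ----------
    carrier_matrix : DataFrame of bool, keys x samples
        From :func:`svburden.classify.build_carrier_matrix`.
    manifest : CohortManifest
        Case/control status and ancestry stratum per sample.
    alpha : float
        Raw-p significance threshold driving the reported significant sets.
    yates : bool
        Apply the Yates continuity correction to the chi-square test.
    risk_only : bool
        Restrict significant sets to risk keys (OR > 1); all keys remain
        in the full results, flagged.
    bonferroni_family : {"per_class", "per_stratum"}
        Whether the correction denominator counts tests within each
        (stratum, region class) family or all tests in the stratum.
    bonferroni_m : int, optional
        Explicit test count overriding the family size.
    """

    def __init__(self, carrier_matrix: pd.DataFrame, manifest: CohortManifest,
                 alpha: float = 0.05, yates: bool = False,
                 risk_only: bool = True,
                 bonferroni_family: str = "per_class",
                 bonferroni_m: int | None = None):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if bonferroni_family not in ("per_class", "per_stratum"):
            raise ValueError(f"unknown bonferroni family {bonferroni_family!r}")
        missing = set(carrier_matrix.columns) - set(manifest.samples)
        if missing:
            raise KeyError(f"matrix samples absent from manifest: "
                           f"{sorted(missing)[:5]}")
        self.matrix = carrier_matrix
        self.manifest = manifest
        self.alpha = alpha
        self.yates = yates
        self.risk_only = risk_only
        self.bonferroni_family = bonferroni_family
        self.bonferroni_m = bonferroni_m

    @classmethod
    def from_assignments(cls, assignments, manifest: CohortManifest,
                         unit: str = "sv_gene", strict: bool = True,
                         **kwargs) -> "SVBurdenModel":
        mat = build_carrier_matrix(assignments, manifest, unit=unit,
                                   strict=strict)
        return cls(mat, manifest, **kwargs)

    def _stratum_frame(self, stratum: str) -> pd.DataFrame:
        cases = self.manifest.stratum_samples(stratum, "case")
        controls = self.manifest.stratum_samples(stratum, "control")
        if not cases or not controls:
            raise ValueError(f"stratum {stratum!r} lacks cases or controls")
        a = self.matrix[cases].sum(axis=1).astype(int)
        c = self.matrix[controls].sum(axis=1).astype(int)
        df = pd.DataFrame({"a": a, "c": c})
        df["b"] = len(cases) - df["a"]
        df["d"] = len(controls) - df["c"]
        df = df[(df["a"] + df["c"]) > 0]  # only keys observed in stratum
        rows = []
        for key, r in df.iterrows():
            t = st.ContingencyTable(int(r["a"]), int(r["b"]),
                                    int(r["c"]), int(r["d"]))
            orv = st.odds_ratio(t)
            lo, hi = st.odds_ratio_ci(t)
            stat, chi2_p = st.chi_square_test(t, yates=self.yates)
            fis_p = st.fisher_exact_test(t)
            rows.append((key, int(r["a"]), int(r["b"]), int(r["c"]),
                         int(r["d"]), orv, lo, hi, stat, chi2_p, fis_p))
        out = pd.DataFrame(
            rows, columns=["key", "a", "b", "c", "d", "odds_ratio",
                           "or_ci_low", "or_ci_high", "chi2_stat",
                           "chi2_p", "fisher_p"])
        out["stratum"] = stratum
        out["is_risk"] = out["odds_ratio"] > 1.0
        # Bonferroni family
        if self.bonferroni_m is not None:
            m = {None: self.bonferroni_m}
            fam = pd.Series(None, index=out.index, dtype=object)
        elif self.bonferroni_family == "per_class" and isinstance(
                self.matrix.index, pd.MultiIndex):
            fam = out["key"].map(lambda k: k[1])
            m = fam.value_counts().to_dict()
        else:
            fam = pd.Series(None, index=out.index, dtype=object)
            m = {None: len(out)}
        out["chi2_p_adj"] = [
            min(1.0, p * m[f]) for p, f in zip(out["chi2_p"], fam)]
        out["fisher_p_adj"] = [
            min(1.0, p * m[f]) for p, f in zip(out["fisher_p"], fam)]
        out["significant"] = (out["chi2_p"] < self.alpha) & (
            out["is_risk"] if self.risk_only else True)
        out = out.sort_values(["chi2_p", "key"],
                              key=lambda s: s.map(str) if s.name == "key" else s,
                              ignore_index=True)
        return out

    def fit(self, strata: Sequence[str] | None = None) -> "SVBurdenResults":
        """Run per-stratum association and cross-strata meta-analysis."""
        strata = list(strata) if strata is not None else self.manifest.strata
        per_stratum = {s: self._stratum_frame(s) for s in strata}
        meta = self._meta(per_stratum) if len(strata) >= 2 else None
        return SVBurdenResults(self, per_stratum, meta)

    def _meta(self, per_stratum: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        by_key: dict = {}
        for stratum, df in per_stratum.items():
            for _, r in df.iterrows():
                by_key.setdefault(r["key"], {})[stratum] = r
        rows = []
        tiny = 5e-324
        for key in sorted(by_key, key=str):
            recs = by_key[key]
            ps = [max(recs[s]["chi2_p"], tiny) for s in sorted(recs)]
            mr = st.meta_combine(ps)
            rows.append((key, ";".join(sorted(recs)), len(ps),
                         mr.statistic, mr.p))
        out = pd.DataFrame(rows, columns=["key", "strata", "k",
                                          "meta_stat", "meta_p"])
        out["meta_p_adj"] = st.bonferroni_adjust(out["meta_p"].tolist())
        return out.sort_values(["meta_p", "key"],
                               key=lambda s: s.map(str) if s.name == "key" else s,
                               ignore_index=True)


class SVBurdenResults:
    """Fitted burden-model results: per-stratum tables, meta table,
    summaries and downstream filters."""

    def __init__(self, model: SVBurdenModel,
                 per_stratum: dict[str, pd.DataFrame],
                 meta: pd.DataFrame | None):
        self.model = model
        self.per_stratum = per_stratum
        self.meta = meta

    @property
    def strata(self) -> list[str]:
        return sorted(self.per_stratum)

    def frame(self, stratum: str) -> pd.DataFrame:
        return self.per_stratum[stratum]

    def significant(self, stratum: str, alpha: float | None = None) -> pd.DataFrame:
        df = self.per_stratum[stratum]
        if alpha is None:
            return df[df["significant"]]
        mask = df["chi2_p"] <= alpha
        if self.model.risk_only:
            mask &= df["is_risk"]
        return df[mask]

    def significant_genes(self, stratum: str, alpha: float | None = None,
                          region_class: str | None = None) -> set[str]:
        df = self.significant(stratum, alpha)
        keys = df["key"]
        if region_class is not None:
            keys = keys[keys.map(lambda k: k[1] == region_class)]
        return {k[0] for k in keys}

    def overlap(self, alpha: float | None = None,
                known_genes: set[str] | None = None) -> dict:
        alpha = self.model.alpha if alpha is None else alpha
        sig = {s: {None: self.significant_genes(s, alpha)} for s in self.strata}
        for s in self.strata:
            for rc in ("exonic", "splicing", "intronic", "intergenic"):
                sig[s][rc] = self.significant_genes(s, alpha, rc)
        by_stratum = {
            s: {("all" if rc is None else rc): g for rc, g in d.items()}
            for s, d in sig.items()}
        return ethnicity_overlap(by_stratum, known_genes=known_genes)

    def geneset_tally(self, gene_sets: Mapping[str, Sequence[str]],
                      alpha: float = 0.05, trend_alpha: float = 0.1) -> pd.DataFrame:
        return geneset_tally(self.per_stratum, gene_sets, alpha=alpha,
                             trend_alpha=trend_alpha)

    def summary(self, max_rows: int = 10) -> str:
        """Human-readable fit summary."""
        lines = ["SV carrier burden association", "=" * 46]
        counts = self.model.manifest.counts()
        for s in self.strata:
            c = counts.get(s, {})
            df = self.per_stratum[s]
            lines.append(
                f"stratum {s}: {c.get('case', 0)} cases / "
                f"{c.get('control', 0)} controls, {len(df)} keys tested, "
                f"{int(df['significant'].sum())} significant "
                f"(raw chi2 p < {self.model.alpha:g}"
                f"{', OR>1' if self.model.risk_only else ''})")
            top = df.head(max_rows)
            for _, r in top.iterrows():
                key = "/".join(map(str, r["key"])) if isinstance(r["key"], tuple) else str(r["key"])
                lines.append(
                    f"  {key:<40s} {r['a']:>3d}/{r['a'] + r['b']:<4d} vs "
                    f"{r['c']:>3d}/{r['c'] + r['d']:<4d} "
                    f"OR={r['odds_ratio']:.2f} "
                    f"[{r['or_ci_low']:.2f},{r['or_ci_high']:.2f}] "
                    f"chi2_p={r['chi2_p']:.3g} fisher_p={r['fisher_p']:.3g}")
        if self.meta is not None:
            nsig = int((self.meta["meta_p"] < self.model.alpha).sum())
            lines.append(f"meta-analysis (Fisher combined, "
                         f"{len(self.meta)} keys): {nsig} with p < "
                         f"{self.model.alpha:g}")
        return "\n".join(lines)

    def to_tsv(self, stratum: str, path: str | Path) -> None:
        df = self.per_stratum[stratum].copy()
        if isinstance(df["key"].iloc[0] if len(df) else None, tuple):
            keydf = pd.DataFrame(df["key"].tolist(), columns=_KEY_COLS)
            df = pd.concat([keydf, df.drop(columns="key")], axis=1)
        df.to_csv(path, sep="\t", index=False)


def rare_recurrent_filter(clusters: Sequence[SVLocusCluster],
                          manifest: CohortManifest,
                          min_case_occurrence: int = 2,
                          max_control_freq: float = 0.005,
                          case_only: bool | None = None) -> list[SVLocusCluster]:
    """Rare recurrent locus filter.

    Keeps clusters with at least ``min_case_occurrence`` case carriers and
    either zero control carriers (``case_only=True``) or a control carrier
    frequency strictly below ``max_control_freq``.  With ``case_only=None``
    the frequency rule applies (which admits case-only clusters too).
    """
    n_controls = sum(1 for ph, _ in manifest.samples.values()
                     if ph == "control")
    out = []
    for cl in clusters:
        case_n = sum(1 for s in cl.carriers
                     if manifest.samples.get(s, ("", ""))[0] == "case")
        ctrl_n = sum(1 for s in cl.carriers
                     if manifest.samples.get(s, ("", ""))[0] == "control")
        if case_n < min_case_occurrence:
            continue
        if case_only:
            if ctrl_n > 0:
                continue
        elif n_controls and ctrl_n / n_controls >= max_control_freq:
            continue
        out.append(cl)
    return out


def ethnicity_overlap(sets_by_stratum: Mapping[str, Mapping[str, set[str]]],
                      known_genes: set[str] | None = None) -> dict:
    """Cross-stratum overlap of significant gene sets.

    ``sets_by_stratum`` maps stratum -> region-class-or-"all" -> gene set.
    Returns per class: the per-stratum sets, their intersection, the
    per-stratum exclusives, and overlap fractions (|intersection| / |set|).
    With ``known_genes`` every set is first intersected with it.
    """
    strata = sorted(sets_by_stratum)
    if len(strata) < 2:
        raise ValueError("overlap needs at least two strata")
    classes = sorted({c for d in sets_by_stratum.values() for c in d})
    out: dict = {}
    for cls in classes:
        sets = {s: set(sets_by_stratum[s].get(cls, set())) for s in strata}
        if known_genes is not None:
            sets = {s: g & known_genes for s, g in sets.items()}
        inter = set.intersection(*sets.values())
        union = set.union(*sets.values())
        out[cls] = {
            "per_stratum": {s: sorted(g) for s, g in sets.items()},
            "sizes": {s: len(g) for s, g in sets.items()},
            "intersection": sorted(inter),
            "exclusive": {s: sorted(g - inter) for s, g in sets.items()},
            "overlap_fraction": {
                s: (len(inter) / len(g) if g else 0.0)
                for s, g in sets.items()},
            "jaccard": len(inter) / len(union) if union else 0.0,
        }
    return out


def read_gmt(source: str | Path | TextIO) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, genes; tab-separated)."""
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
    else:
        fh = source
    try:
        sets: dict[str, list[str]] = {}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3 or not cols[0]:
                continue
            sets[cols[0]] = [g for g in cols[2:] if g]
    finally:
        if close:
            fh.close()
    return sets


def geneset_tally(per_stratum: Mapping[str, pd.DataFrame],
                  gene_sets: Mapping[str, Sequence[str]],
                  alpha: float = 0.05, trend_alpha: float = 0.1) -> pd.DataFrame:
    """Membership tally: which set members reach significance or a trend.

    One row per (set, gene, stratum, region class, sv type) whose chi-square
    p is <= ``trend_alpha``; the ``tier`` column distinguishes significant
    (p <= alpha) from trend (alpha < p <= trend_alpha) hits.
    """
    rows = []
    for set_name, genes in gene_sets.items():
        members = set(genes)
        if not members:
            logger.warning("gene set %r is empty; skipped", set_name)
            continue
        for stratum, df in per_stratum.items():
            for _, r in df.iterrows():
                key = r["key"]
                gene = key[0] if isinstance(key, tuple) else str(key)
                if gene not in members or r["chi2_p"] > trend_alpha:
                    continue
                rc = key[1] if isinstance(key, tuple) else ""
                svt = key[2] if isinstance(key, tuple) else ""
                tier = "significant" if r["chi2_p"] <= alpha else "trend"
                rows.append((set_name, gene, stratum, rc, svt,
                             r["odds_ratio"], r["chi2_p"], tier))
    return pd.DataFrame(rows, columns=["gene_set", "gene_id", "stratum",
                                       "region_class", "sv_type",
                                       "odds_ratio", "chi2_p", "tier"])
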