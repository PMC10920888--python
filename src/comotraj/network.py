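"""Sex-specific multilayer comorbidity network construction.

Nodes are (ICD-10 code, ten-year age group) pairs — eight layers, ages
0–9 through 70–79.  Two link types:

* **Intralayer links** (same layer): for every diagnosis pair the cohort
  is stratified into six 2-year calendar windows (2003–2014); each
  stratum with every 2x2 cell >= ``min_cell_count`` enters a
  Mantel–Haenszel pooled risk ratio and a CMH independence test.  Pairs
  with RR > ``rr_threshold`` and p < ``p_threshold`` become bidirectional
  links, each direction weighted by its own orientation of the pooled RR.
* **Interlayer links** (lower to higher layer): the observation period is
  split into frames T1 = 2003–2008 and T2 = 2009–2014, and the weight of
  i@alpha -> j@beta is the conditional-risk ratio
  P(j in beta during T2 | i in alpha during T1) / P(j in beta during T2),
  over cohort patients observed in beta during T2.  Links are kept when
  the ratio exceeds ``interlayer_min_weight`` with at least
  ``interlayer_min_exposed`` exposed patients; i == j is allowed and
  encodes disease persistence across decades.

Nodes without intralayer links are removed, then nodes lacking an inbound
or outbound link (iterated to a fixed point); finally incoming weights are
normalized to sum to one per node and link type.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from ._icd import SENTINEL, node_label, parse_node_label
from .cmh import cmh_test, mh_risk_ratio, cmh_pool  # noqa: F401 (re-export)

FILTER_MODES = ("intralayer_only", "in_and_out", "both_stages")


@dataclass(frozen=True)
class BuilderConfig:
    rr_threshold: float = 1.5
    p_threshold: float = 0.05
    #: "more than four patients in each subgroup": every 2x2 cell >= 5
    min_cell_count: int = 5
    t1: tuple = (2003, 2008)
    t2: tuple = (2009, 2014)
    interlayer_min_weight: float = 1.5
    interlayer_min_exposed: int = 5
    node_filter_mode: str = "both_stages"
    #: finite stand-in weight when a pooled RR denominator is zero
    rr_cap: float = 100.0
    #: optional Benjamini–Hochberg correction of intralayer p-values
    bh_correction: bool = False

    def __post_init__(self):
        if self.node_filter_mode not in FILTER_MODES:
            raise ValueError(f"unknown filter mode {self.node_filter_mode!r}")
        if self.t1[1] + 1 != self.t2[0]:
            raise ValueError("T1 and T2 must be adjacent")

    @property
    def windows(self):
        """Six 2-year stratification windows partitioning T1 ∪ T2."""
        lo, hi = self.t1[0], self.t2[1]
        return tuple((y, y + 1) for y in range(lo, hi, 2))

    def window_index(self, year):
        return (np.asarray(year) - self.t1[0]) // 2

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ContingencyStratum:
    """One 2x2 table: a=both, b=i only, c=j only, d=neither."""

    stratum_id: tuple  # (window, age_group, sex)
    a: int
    b: int
    c: int
    d: int
    used: bool = True

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationRecord:
    i: tuple  # (code, layer)
    j: tuple
    strata: tuple
    rr: float
    rr_reverse: float
    p_value: float
    n_strata_used: int


class MultilayerNetwork:
    """Directed weighted multilayer network over (code, layer) nodes."""

    def __init__(self, graph: nx.DiGraph, sex: str, config: BuilderConfig,
                 provenance: dict | None = None):
        self.graph = graph
        self.sex = sex
        self.config = config
        self.provenance = dict(provenance or {})
        self.provenance.setdefault("config_hash", config.config_hash())

    @property
    def nodes(self):
        return set(self.graph.nodes)

    def edges(self, kind=None):
        return [
            (u, v, d) for u, v, d in self.graph.edges(data=True)
            if kind is None or d["type"] == kind
        ]

    @property
    def intralayer_links(self):
        return self.edges("intra")

    @property
    def interlayer_links(self):
        return self.edges("inter")

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "source": node_label(*u),
                "target": node_label(*v),
                "type": d["type"],
                "raw_weight": d["raw_weight"],
                "norm_weight": d.get("norm_weight", np.nan),
            }
            for u, v, d in sorted(self.graph.edges(data=True),
                                  key=lambda e: (e[0], e[1]))
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "type", "raw_weight", "norm_weight"]
        )

    def to_graphml(self, path):
        g = nx.DiGraph()
        g.graph["sex"] = self.sex
        g.graph["config_hash"] = self.provenance["config_hash"]
        for (code, layer) in self.graph.nodes:
            g.add_node(node_label(code, layer), code=code, layer=int(layer))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(node_label(*u), node_label(*v), type=d["type"],
                       raw_weight=float(d["raw_weight"]),
                       norm_weight=float(d.get("norm_weight", np.nan)))
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path, config: BuilderConfig | None = None):
        g = nx.read_graphml(path)
        graph = nx.DiGraph()
        for n, d in g.nodes(data=True):
            graph.add_node((d.get("code") or parse_node_label(n)[0],
                            int(d.get("layer") or parse_node_label(n)[1])))
        for u, v, d in g.edges(data=True):
            gu = (g.nodes[u]["code"], int(g.nodes[u]["layer"]))
            gv = (g.nodes[v]["code"], int(g.nodes[v]["layer"]))
            graph.add_edge(gu, gv, type=d["type"],
                           raw_weight=float(d["raw_weight"]),
                           norm_weight=float(d.get("norm_weight", np.nan)))
        return cls(graph, g.graph.get("sex", "unknown"),
                   config or BuilderConfig())


# ---------------------------------------------------------------------------
# intralayer links

def _presence(sub: pd.DataFrame):
    """Boolean patient-by-code presence matrix for one stratum."""
    pats, _ = pd.factorize(sub["patient_id"], sort=True)
    codes_idx, codes = pd.factorize(sub["code"], sort=True)
    x = np.zeros((pats.max() + 1 if len(pats) else 0, len(codes)), dtype=bool)
    x[pats, codes_idx] = True
    return x, list(codes)


def build_contingency(events, pair, layer, sex, cfg: BuilderConfig = BuilderConfig()):
    """Stratified 2x2 tables for one diagnosis pair in one layer.

    The denominator of each stratum is the distinct cohort patients of
    the given sex with at least one event in that layer and 2-year
    window; strata with any cell below ``min_cell_count`` are marked
    unused.
    """
    ci, cj = pair
    if ci == cj:
        raise ValueError("pair must be two distinct codes")
    ev = events[(events["sex"] == sex) & (events["age_group"] == layer)]
    ev = ev[(ev["year"] >= cfg.t1[0]) & (ev["year"] <= cfg.t2[1])]
    strata = []
    for w, (y0, y1) in enumerate(cfg.windows):
        sub = ev[(ev["year"] >= y0) & (ev["year"] <= y1)]
        pats = sub.groupby("patient_id")["code"].apply(set)
        if pats.empty:
            continue
        has_i = pats.apply(lambda s: ci in s)
        has_j = pats.apply(lambda s: cj in s)
        a = int((has_i & has_j).sum())
        b = int((has_i & ~has_j).sum())
        c = int((~has_i & has_j).sum())
        d = int((~has_i & ~has_j).sum())
        used = min(a, b, c, d) >= cfg.min_cell_count
        strata.append(ContingencyStratum((w, layer, sex), a, b, c, d, used))
    return strata


def intralayer_links(events, cfg: BuilderConfig = BuilderConfig(), sex="male"):
    """Screen every same-layer diagnosis pair; emit bidirectional links.

    Returns ``(edges, audit)``: directed edge tuples
    ``((code_i, layer), (code_j, layer), raw_weight)`` in both
    orientations for every pair passing RR > threshold and p < threshold
    in at least one orientation, plus a per-pair audit table (including
    skipped pairs with no usable stratum).
    """
    ev = events[(events["sex"] == sex)
                & (events["year"] >= cfg.t1[0]) & (events["year"] <= cfg.t2[1])]
    edges, audit = [], []
    for layer in sorted(ev["age_group"].unique()):
        evl = ev[ev["age_group"] == layer]
        evl = evl.assign(window=cfg.window_index(evl["year"].to_numpy()))
        counts = {}  # window -> (a, b, c, d arrays over pair index), codes
        codes_all = sorted(evl["code"].unique())
        if len(codes_all) < 2:
            continue
        code_pos = {c: k for k, c in enumerate(codes_all)}
        iu, ju = np.triu_indices(len(codes_all), k=1)
        A = []
        for w in range(len(cfg.windows)):
            sub = evl[evl["window"] == w][["patient_id", "code"]].drop_duplicates()
            x = np.zeros((sub["patient_id"].nunique(), len(codes_all)), dtype=bool)
            if len(sub):
                pats, _ = pd.factorize(sub["patient_id"], sort=True)
                cols = sub["code"].map(code_pos).to_numpy()
                x[pats, cols] = True
            n_pat = x.shape[0]
            xf = x.astype(np.int64)
            cooc = xf.T @ xf
            ni = xf.sum(axis=0)
            a = cooc[iu, ju]
            b = ni[iu] - a
            c = ni[ju] - a
            d = n_pat - ni[iu] - ni[ju] + a
            A.append((a, b, c, d))
        a = np.stack([t[0] for t in A], axis=1).astype(float)
        b = np.stack([t[1] for t in A], axis=1).astype(float)
        c = np.stack([t[2] for t in A], axis=1).astype(float)
        d = np.stack([t[3] for t in A], axis=1).astype(float)
        usable = np.minimum.reduce([a, b, c, d]) >= cfg.min_cell_count
        n_used = usable.sum(axis=1)
        has = n_used > 0
        rr_ij = np.full(len(iu), np.nan)
        rr_ji = np.full(len(iu), np.nan)
        pval = np.full(len(iu), np.nan)
        if has.any():
            rr_ij[has] = mh_risk_ratio(a[has], b[has], c[has], d[has], usable[has])
            rr_ji[has] = mh_risk_ratio(a[has], c[has], b[has], d[has], usable[has])
            _, pval[has] = cmh_test(a[has], b[has], c[has], d[has], usable[has])
        p_adj = pval.copy()
        if cfg.bh_correction and has.any():
            from statsmodels.stats.multitest import multipletests
            p_adj[has] = multipletests(pval[has], method="fdr_bh")[1]
        sig = p_adj < cfg.p_threshold
        gate = has & sig & (
            (np.nan_to_num(rr_ij) > cfg.rr_threshold)
            | (np.nan_to_num(rr_ji) > cfg.rr_threshold)
        )
        for k in range(len(iu)):
            ci, cj = codes_all[iu[k]], codes_all[ju[k]]
            audit.append({
                "layer": int(layer), "code_i": ci, "code_j": cj,
                "n_strata_used": int(n_used[k]),
                "rr_ij": rr_ij[k], "rr_ji": rr_ji[k], "p_value": pval[k],
                "emitted": bool(gate[k]),
            })
            if gate[k]:
                wij = float(min(rr_ij[k], cfg.rr_cap))
                wji = float(min(rr_ji[k], cfg.rr_cap))
                edges.append(((ci, int(layer)), (cj, int(layer)), wij))
                edges.append(((cj, int(layer)), (ci, int(layer)), wji))
    cols = ["layer", "code_i", "code_j", "n_strata_used", "rr_ij", "rr_ji",
            "p_value", "emitted"]
    return edges, pd.DataFrame(audit, columns=cols)


# ---------------------------------------------------------------------------
# interlayer links

def interlayer_links(events, cfg: BuilderConfig = BuilderConfig(), sex="male"):
    """Conditional-risk-ratio links from lower to higher layers.

    Weight of (i, alpha) -> (j, beta) is P(j@beta in T2 | i@alpha in T1) /
    P(j@beta in T2) over cohort patients of the sex observed in beta
    during T2.
    """
    ev = events[events["sex"] == sex]
    t1 = ev[(ev["year"] >= cfg.t1[0]) & (ev["year"] <= cfg.t1[1])]
    t2 = ev[(ev["year"] >= cfg.t2[0]) & (ev["year"] <= cfg.t2[1])]
    edges, audit = [], []
    for beta in sorted(t2["age_group"].unique()):
        yb = t2[t2["age_group"] == beta][["patient_id", "code"]].drop_duplicates()
        if yb.empty:
            continue
        pats_b = np.sort(yb["patient_id"].unique())
        pos_b = {p: k for k, p in enumerate(pats_b)}
        codes_b = sorted(yb["code"].unique())
        Y = np.zeros((len(pats_b), len(codes_b)), dtype=np.int64)
        Y[yb["patient_id"].map(pos_b).to_numpy(),
          yb["code"].map({c: k for k, c in enumerate(codes_b)}).to_numpy()] = 1
        n_j = Y.sum(axis=0)
        n_obs = len(pats_b)
        for alpha in sorted(t1["age_group"].unique()):
            if alpha >= beta:
                continue
            xa = t1[(t1["age_group"] == alpha)
                    & (t1["patient_id"].isin(pos_b))][
                ["patient_id", "code"]].drop_duplicates()
            if xa.empty:
                continue
            codes_a = sorted(xa["code"].unique())
            X = np.zeros((len(pats_b), len(codes_a)), dtype=np.int64)
            X[xa["patient_id"].map(pos_b).to_numpy(),
              xa["code"].map({c: k for k, c in enumerate(codes_a)}).to_numpy()] = 1
            exposed = X.sum(axis=0)
            C = X.T @ Y
            with np.errstate(divide="ignore", invalid="ignore"):
                p_cond = C / exposed[:, None]
                p_base = n_j / n_obs
                w = p_cond / p_base[None, :]
            ok = (exposed[:, None] >= cfg.interlayer_min_exposed) & (n_j[None, :] > 0)
            keep = ok & (w > cfg.interlayer_min_weight)
            for ia, jb in zip(*np.nonzero(ok)):
                audit.append({
                    "code_i": codes_a[ia], "layer_i": int(alpha),
                    "code_j": codes_b[jb], "layer_j": int(beta),
                    "n_exposed": int(exposed[ia]),
                    "weight": float(w[ia, jb]),
                    "emitted": bool(keep[ia, jb]),
                })
                if keep[ia, jb]:
                    edges.append(((codes_a[ia], int(alpha)),
                                  (codes_b[jb], int(beta)),
                                  float(w[ia, jb])))
    cols = ["code_i", "layer_i", "code_j", "layer_j", "n_exposed", "weight",
            "emitted"]
    return edges, pd.DataFrame(audit, columns=cols)


# ---------------------------------------------------------------------------
# assembly, filtering, normalization

def filter_nodes(net: MultilayerNetwork, mode: str | None = None) -> MultilayerNetwork:
    """Node filtering: drop nodes without intralayer links and/or nodes
    lacking an inbound or outbound link (iterated to a fixed point)."""
    mode = mode or net.config.node_filter_mode
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}")
    g = net.graph.copy()
    if mode in ("intralayer_only", "both_stages"):
        keep = {
            n for n in g.nodes
            if any(d["type"] == "intra"
                   for _, _, d in g.in_edges(n, data=True))
            or any(d["type"] == "intra"
                   for _, _, d in g.out_edges(n, data=True))
        }
        g.remove_nodes_from(set(g.nodes) - keep)
    if mode in ("in_and_out", "both_stages"):
        while True:
            bad = [n for n in g.nodes
                   if g.in_degree(n) == 0 or g.out_degree(n) == 0]
            if not bad:
                break
            g.remove_nodes_from(bad)
    if g.number_of_nodes() == 0:
        raise ValueError("node filtering left an empty network")
    return MultilayerNetwork(g, net.sex, net.config, net.provenance)


def normalize_weights(net: MultilayerNetwork) -> MultilayerNetwork:
    """Divide each incoming weight by the per-(target, link-type) sum."""
    g = net.graph.copy()
    for node in g.nodes:
        for kind in ("intra", "inter"):
            incoming = [(u, d) for u, _, d in g.in_edges(node, data=True)
                        if d["type"] == kind]
            total = sum(d["raw_weight"] for _, d in incoming)
            for u, d in incoming:
                g[u][node]["norm_weight"] = d["raw_weight"] / total
    # conservation audit
    for node in g.nodes:
        for kind in ("intra", "inter"):
            s = sum(d["norm_weight"] for _, _, d in g.in_edges(node, data=True)
                    if d["type"] == kind)
            if s and abs(s - 1.0) > 1e-9:
                raise AssertionError(f"normalization broke at {node} ({kind})")
    return MultilayerNetwork(g, net.sex, net.config, net.provenance)


def build_network(events, cfg: BuilderConfig = BuilderConfig(), sex="male",
                  filter_and_normalize=True):
    """Full network assembly for one sex.

    Returns ``(net, audits)`` where ``audits`` holds the intralayer and
    interlayer association tables.
    """
    intra, intra_audit = intralayer_links(events, cfg, sex)
    inter, inter_audit = interlayer_links(events, cfg, sex)
    g = nx.DiGraph()
    ev = events[events["sex"] == sex]
    for code, layer in (
        ev[["code", "age_group"]].drop_duplicates().itertuples(index=False)
    ):
        g.add_node((code, int(layer)))
    for u, v, w in intra:
        g.add_edge(u, v, type="intra", raw_weight=w)
    for u, v, w in inter:
        g.add_edge(u, v, type="inter", raw_weight=w)
    net = MultilayerNetwork(
        g, sex, cfg,
        {"n_events": int(len(ev)), "n_patients": int(ev["patient_id"].nunique())},
    )
    if filter_and_normalize:
        net = normalize_weights(filter_nodes(net))
    return net, {"intralayer": intra_audit, "interlayer": inter_audit}


# ---------------------------------------------------------------------------
# summary statistics

def network_summary(net: MultilayerNetwork):
    """Whole-network and per-layer summary statistics.

    Path-based metrics are computed on the largest weakly connected
    component (flagged when the network is disconnected); modularity uses
    a greedy reference partition of the undirected collapse.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        w = d.get("norm_weight", d["raw_weight"])
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    degrees = [deg for _, deg in g.degree()]
    connected = nx.is_connected(und) if und.number_of_nodes() else False
    comp = max(nx.connected_components(und), key=len)
    sub = und.subgraph(comp)
    apl = nx.average_shortest_path_length(sub) if sub.number_of_nodes() > 1 else 0.0
    betw = nx.betweenness_centrality(g)
    clos = nx.closeness_centrality(g)
    try:
        assort = nx.degree_assortativity_coefficient(g)
    except (ValueError, ZeroDivisionError):
        assort = float("nan")
    communities = list(nx.community.greedy_modularity_communities(und))
    modularity = (
        nx.community.modularity(und, communities) if len(communities) > 1 else 0.0
    )
    summary = {
        "n_nodes": g.number_of_nodes(),
        "n_intralayer_links": sum(1 for _, _, d in g.edges(data=True)
                                  if d["type"] == "intra"),
        "n_interlayer_links": sum(1 for _, _, d in g.edges(data=True)
                                  if d["type"] == "inter"),
        "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
        "sd_degree": float(np.std(degrees)) if degrees else 0.0,
        "assortativity": float(assort),
        "average_path_length": float(apl),
        "path_length_on_largest_component": not connected,
        "mean_betweenness": float(np.mean(list(betw.values()))),
        "mean_closeness": float(np.mean(list(clos.values()))),
        "clustering_coefficient": float(nx.average_clustering(und)),
        "density": float(nx.density(g)),
        "modularity": float(modularity),
    }
    per_layer = []
    for layer in range(1, 9):
        nodes = [n for n in g.nodes if n[1] == layer]
        if not nodes:
            continue
        intra = [e for e in g.edges(nodes, data=True) if e[2]["type"] == "intra"]
        inter_out = [e for e in g.out_edges(nodes, data=True)
                     if e[2]["type"] == "inter"]
        inter_in = [e for e in g.in_edges(nodes, data=True)
                    if e[2]["type"] == "inter"]
        per_layer.append({
            "layer": layer,
            "n_nodes": len(nodes),
            "n_intralayer": len(intra),
            "n_interlayer_in": len(inter_in),
            "n_interlayer_out": len(inter_out),
            "mean_degree": float(np.mean([g.degree(n) for n in nodes])),
        })
    return summary, pd.DataFrame(per_layer)
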