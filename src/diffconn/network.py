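"""Co-expression networks, normalized connectivity K, and DiffK hub calling.

The pipeline builds one Pearson-correlation network per condition
(IF-pre, IF-post, ID-pre, ID-post) over a combined gene set.  Connectivity
for gene ``i`` is the unsigned sum

    K_i = sum_{j != i} |r_ij|,

normalized by the network's maximum, ``k_i = K_i / max_j K_j`` (so every
network has at least one gene at exactly k = 1).  Differential connectivity
is ``DiffK_i = k_post,i - k_pre,i``; a gene is a *hub* when
``|DiffK| > 0.2`` and its permutation p < 0.05.

Because the larger group's samples are merged down to three profiles for
network estimation (six samples paired by expression-profile similarity,
each merged profile the mean of its pair), correlations are computed from
as few as three points and are extremely noisy; the permutation p guards
the interpretation.  The permutation null swaps pre/post labels within
patients; when the number of patients admits it (2^n <= n_perm) all sign
patterns are enumerated for an exact, deterministic p.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "NetworkState",
    "combine_gene_set",
    "merge_similar_samples",
    "build_network",
    "diffk",
    "diffk_pvalues",
    "classify_sectors",
    "hub_table",
    "export_network",
]


@dataclass
class NetworkState:
    """One condition's correlation network with connectivity measures."""

    label: str
    corr: pd.DataFrame          # genes x genes Pearson r
    K: pd.Series                # raw connectivity, diagonal excluded
    k: pd.Series                # K normalized by its maximum
    dropped: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.corr.index)

    def edges(self, threshold: float) -> pd.DataFrame:
        """Signed edge list with ``|r| >= threshold`` (gene1 < gene2)."""
        r = self.corr.to_numpy()
        g = np.asarray(self.corr.index)
        iu = np.triu_indices(len(g), k=1)
        keep = np.abs(r[iu]) >= threshold
        rows = {
            "gene1": g[iu[0][keep]],
            "gene2": g[iu[1][keep]],
            "r": r[iu][keep],
        }
        out = pd.DataFrame(rows)
        out["sign"] = np.where(out["r"] >= 0, "+", "-")
        return out


def combine_gene_set(de_if: list[str], de_id: list[str]) -> list[str]:
    """Union of the two groups' DE gene lists, sorted for a stable order."""
    union = sorted(set(de_if) | set(de_id))
    if not union:
        raise ValueError("empty combined gene set: no network possible")
    return union


def _greedy_pairs(X: np.ndarray) -> list[tuple[int, int]]:
    """Pair columns of ``X`` greedily by smallest 1 - Pearson distance."""
    d = 1.0 - np.corrcoef(X.T)
    np.fill_diagonal(d, np.inf)
    n = d.shape[0]
    unused = set(range(n))
    pairs = []
    while len(unused) > 1:
        sub = [(d[i, j], i, j) for i in unused for j in unused if i < j]
        _, i, j = min(sub)
        pairs.append((i, j))
        unused -= {i, j}
    return pairs


def merge_similar_samples(
    study: ExpressionStudy, group: str = "IF", target: int = 3
) -> ExpressionStudy:
    """Merge a group's samples pairwise down to ``target`` profiles per
    timepoint, pairing mutually closest samples (1 - Pearson distance).

    Each merged profile is the arithmetic mean of its pair.  Pairing is
    computed per timepoint independently; merged pre and post profiles are
    matched into pseudo-patients by patient overlap (greedy), and the full
    merging map is recorded in the returned study's ``meta``.
    """
    sub = study.subset_group(group)
    pair_members: dict[str, list[frozenset]] = {}
    merged_profiles: dict[str, list[np.ndarray]] = {}
    for tp in ("pre", "post"):
        cols = sub.samples_for(timepoint=tp)
        if len(cols) != 2 * target:
            raise ValueError(
                f"group {group!r} has {len(cols)} {tp} samples; cannot pair down to {target}"
            )
        X = sub.matrix[cols].to_numpy()
        pairs = _greedy_pairs(X)
        pair_members[tp] = [
            frozenset(sub.design.loc[[cols[i], cols[j]], "patient_id"]) for i, j in pairs
        ]
        merged_profiles[tp] = [X[:, [i, j]].mean(axis=1) for i, j in pairs]

    # match pre and post pairs into pseudo-patients by patient overlap
    order_pre = sorted(range(target), key=lambda i: sorted(pair_members["pre"][i]))
    assignment: dict[int, int] = {}
    used_post: set[int] = set()
    for i in order_pre:
        best = max(
            (j for j in range(target) if j not in used_post),
            key=lambda j: (len(pair_members["pre"][i] & pair_members["post"][j]),
                           -j),
        )
        assignment[i] = best
        used_post.add(best)

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    merge_map: dict[str, list[str]] = {}
    for unit, i in enumerate(order_pre, start=1):
        pid = f"{group}-M{unit}"
        j = assignment[i]
        for tp, idx in (("pre", i), ("post", j)):
            sid = f"{pid}_{tp}"
            columns[sid] = merged_profiles[tp][idx]
            design_rows.append((sid, pid, group, tp))
            merge_map[sid] = sorted(pair_members[tp][idx])
    log.info("merged %s samples: %s", group, merge_map)
    matrix = pd.DataFrame(columns, index=sub.matrix.index)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "patient_id", "group", "timepoint"]
    ).set_index("sample_id")
    return ExpressionStudy(matrix, design, meta={"merge_map": merge_map})


def build_network(profiles: pd.DataFrame, genes: list[str] | None = None,
                  label: str = "") -> NetworkState:
    """Pearson network over one condition's profiles (genes x samples).

    Genes with zero variance across the profiles are dropped with a
    warning before the correlation is computed.  Requires >= 3 profiles.
    """
    if genes is not None:
        missing = set(genes) - set(profiles.index)
        if missing:
            raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]} ...")
        profiles = profiles.loc[list(genes)]
    if profiles.shape[1] < 3:
        raise ValueError(f"need >= 3 profiles, got {profiles.shape[1]}")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    dropped = list(profiles.index[~keep])
    if dropped:
        log.warning("%s: dropped %d zero-variance gene(s)", label or "network", len(dropped))
    idx = profiles.index[keep]
    r = np.corrcoef(X[keep])
    r = np.clip(r, -1.0, 1.0)
    A = np.abs(r)
    np.fill_diagonal(A, 0.0)
    K = A.sum(axis=1)
    kmax = K.max()
    k = K / kmax if kmax > 0 else np.zeros_like(K)
    return NetworkState(
        label=label,
        corr=pd.DataFrame(r, index=idx, columns=idx),
        K=pd.Series(K, index=idx),
        k=pd.Series(k, index=idx),
        dropped=dropped,
    )


def diffk(pre: NetworkState, post: NetworkState) -> pd.DataFrame:
    """Per-gene k_pre, k_post and DiffK = k_post - k_pre on the shared genes."""
    common = [g for g in pre.genes if g in set(post.genes)]
    if not common:
        raise ValueError("pre and post networks share no genes")
    lost = (set(pre.genes) | set(post.genes)) - set(common)
    if lost:
        log.warning("%d gene(s) present in only one network dropped", len(lost))
    out = pd.DataFrame(
        {
            "k_pre": pre.k.loc[common],
            "k_post": post.k.loc[common],
        }
    )
    out["diffk"] = out["k_post"] - out["k_pre"]
    return out


def _group_diffk(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    genes: list[str],
    merge_to: int | None,
    group: str,
) -> pd.Series:
    study = ExpressionStudy(matrix, design.copy())
    if merge_to is not None:
        study = merge_similar_samples(study, group=group, target=merge_to)
    pre = build_network(study.condition_matrix(group, "pre"), genes, label=f"{group}-pre")
    post = build_network(study.condition_matrix(group, "post"), genes, label=f"{group}-post")
    return diffk(pre, post)["diffk"].reindex(genes)


def diffk_pvalues(
    study: ExpressionStudy,
    genes: list[str],
    group: str,
    n_perm: int = 999,
    seed: int | None = 0,
    merge_to: int | None = None,
) -> pd.DataFrame:
    """Observed DiffK per gene with a pre/post label-swap permutation p.

    The null swaps pre and post within each patient (before any sample
    merging, which is recomputed per permutation).  With ``n`` patients
    there are 2^n sign patterns; when ``2^n <= n_perm`` they are enumerated
    exhaustively and ``p = #{|DiffK*| >= |DiffK|} / 2^n`` (the identity
    pattern makes p strictly positive).  Otherwise ``n_perm`` random
    patterns are drawn and the add-one estimator
    ``p = (1 + #{|DiffK*| >= |DiffK|}) / (n_perm + 1)`` is used.

    Two-sided by construction; p is in (0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable permutation p")
    sub = study.subset_group(group)
    patients = sub.patients()
    pre_cols = {p: None for p in patients}
    post_cols = dict(pre_cols)
    for sid, row in sub.design.iterrows():
        (pre_cols if row["timepoint"] == "pre" else post_cols)[row["patient_id"]] = sid

    base = sub.matrix
    design = sub.design

    def permuted_diffk(flips: np.ndarray) -> pd.Series:
        mat = base.copy()
        for f, pid in zip(flips, patients):
            if f:
                a, b = pre_cols[pid], post_cols[pid]
                mat[a], mat[b] = base[b].to_numpy(), base[a].to_numpy()
        return _group_diffk(mat, design, genes, merge_to, group)

    observed = permuted_diffk(np.zeros(len(patients), dtype=bool))
    obs_abs = observed.abs().to_numpy()

    n_pat = len(patients)
    exact = 2 ** n_pat <= n_perm
    exceed = np.zeros(len(genes))
    total = 0
    if exact:
        patterns = itertools.product([False, True], repeat=n_pat)
    else:
        rng = np.random.default_rng(seed)
        patterns = (rng.random(n_pat) < 0.5 for _ in range(n_perm))
    for flips in patterns:
        dk = permuted_diffk(np.asarray(flips, dtype=bool)).abs().to_numpy()
        exceed += np.where(np.isnan(dk), 0.0, dk >= obs_abs - 1e-12)
        total += 1
    if exact:
        p = exceed / total
    else:
        p = (1.0 + exceed) / (total + 1.0)
    p = np.where(np.isnan(obs_abs), np.nan, p)  # genes dropped in the observed networks
    out = pd.DataFrame({"diffk": observed, "p": p}, index=pd.Index(genes, name="gene"))
    out.attrs["exact"] = exact
    return out


def classify_sectors(
    records: pd.DataFrame, diffk_thr: float = 0.2, p_thr: float = 0.05
) -> pd.Series:
    """Sector of the (DiffK, p) plane cut at DiffK = +-thr and p = p_thr.

    Numbering (documented convention; the two significant flanks are 1 and 3):

    ========  =====================  ==========
    sector    DiffK                  p
    ========  =====================  ==========
    1         > +thr                 < p_thr
    2         > +thr                 >= p_thr
    3         < -thr                 < p_thr
    4         < -thr                 >= p_thr
    5         within [-thr, +thr]    >= p_thr
    6         within [-thr, +thr]    < p_thr
    ========  =====================  ==========
    """
    dk = records["diffk"].to_numpy()
    p = records["p"].to_numpy()
    sig = p < p_thr
    sector = np.full(len(records), 5)
    sector[(dk > diffk_thr) & sig] = 1
    sector[(dk > diffk_thr) & ~sig] = 2
    sector[(dk < -diffk_thr) & sig] = 3
    sector[(dk < -diffk_thr) & ~sig] = 4
    sector[(np.abs(dk) <= diffk_thr) & sig] = 6
    return pd.Series(sector, index=records.index, name="sector")


def hub_table(
    study: ExpressionStudy,
    genes: list[str],
    group: str,
    n_perm: int = 999,
    seed: int | None = 0,
    merge_to: int | None = None,
    diffk_thr: float = 0.2,
    p_thr: float = 0.05,
) -> pd.DataFrame:
    """Full per-gene record: k_pre, k_post, DiffK, permutation p, sector,
    hub flag, for one group."""
    sub = study.subset_group(group)
    working = (
        merge_similar_samples(sub, group=group, target=merge_to)
        if merge_to is not None
        else sub
    )
    pre = build_network(working.condition_matrix(group, "pre"), genes, label=f"{group}-pre")
    post = build_network(working.condition_matrix(group, "post"), genes, label=f"{group}-post")
    base = diffk(pre, post)
    perm = diffk_pvalues(
        study, genes, group, n_perm=n_perm, seed=seed, merge_to=merge_to
    )
    out = base.join(perm["p"])
    out["sector"] = classify_sectors(out, diffk_thr=diffk_thr, p_thr=p_thr)
    out["hub"] = out["sector"].isin([1, 3])
    out.attrs["exact"] = perm.attrs.get("exact")
    return out


def export_network(
    state: NetworkState,
    records: pd.DataFrame | None = None,
    edge_threshold: float = 0.8,
    directions: pd.Series | None = None,
):
    """Node and edge tables (and the corresponding graph) for viewers.

    Node rows carry normalized connectivity, the hub flag, and the DE
    direction (the red/green up-/down-regulation semantics of network
    figures).  Edges keep the sign of the correlation.
    """
    if not (0.0 < edge_threshold <= 1.0):
        raise ValueError("edge_threshold must lie in (0, 1]")
    import networkx as nx

    nodes = pd.DataFrame(index=pd.Index(state.genes, name="gene"))
    nodes["k"] = state.k
    nodes["hub"] = (
        records["hub"].reindex(state.genes).fillna(False).astype(bool)
        if records is not None and "hub" in records
        else False
    )
    nodes["direction"] = (
        directions.reindex(state.genes) if directions is not None else pd.NA
    )
    edges = state.edges(edge_threshold)
    graph = nx.Graph()
    for gene, row in nodes.iterrows():
        graph.add_node(gene, k=float(row["k"]), hub=bool(row["hub"]))
    for _, row in edges.iterrows():
        graph.add_edge(row["gene1"], row["gene2"], r=float(row["r"]), sign=row["sign"])
    return nodes, edges, graph
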