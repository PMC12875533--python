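"""Co-CRE modules, hub CREs and locus enrichment.

The CRE-CRE attention network is clustered with the Louvain algorithm
(resolution 1.0, seeded). Hubs are extracted at three levels: network
hubs (CREs of the globally top-weighted pairs), module hubs (top pairs
within each Louvain module) and degree hubs (top weighted degree).
Enrichment of a hub set in external loci (GWAS SNPs, eQTLs, super
enhancers, ...) is the overlap-fraction ratio against all CREs, with an
empirical permutation p-value. Genes whose TSS falls within +/-2 Mbp of a
hub CRE are its regulated genes (HCGs).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_graph import NodeSet, TypedEdgeSet

HCG_WINDOW = 2_000_000  # bp around a hub CRE


@dataclass
class CREModulePartition:
    module_of: dict[str, int]
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.module_of.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module: int) -> list[str]:
        return sorted(c for c, m in self.module_of.items() if m == module)


@dataclass
class HubSets:
    network_hubs: list[str]
    module_hubs: list[str]
    degree_hubs: list[str]


def _graph_from_edges(cre_edges: TypedEdgeSet) -> nx.Graph:
    if len(cre_edges) == 0:
        raise ValueError("empty CRE-CRE edge set")
    if (cre_edges.weights < 0).any():
        raise ValueError("edge weights must be non-negative")
    g = nx.Graph()
    for (s, t), w in zip(cre_edges.pairs, cre_edges.weights):
        g.add_edge(s, t, weight=float(w))
    return g


def louvain_modules(cre_edges: TypedEdgeSet, seed: int = 0,
                    resolution: float = 1.0) -> CREModulePartition:
    """Louvain community detection on the weighted CRE-CRE graph.

    Deterministic for a fixed seed; the returned modularity is computed
    on the same weighted graph that was clustered and is at least the
    modularity of the all-singletons partition.
    """
    g = _graph_from_edges(cre_edges)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed)
    mod = nx.community.modularity(g, comms, weight="weight",
                                  resolution=resolution)
    module_of = {}
    for m, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            module_of[node] = m
    return CREModulePartition(module_of, float(mod))


def extract_hubs(cre_edges: TypedEdgeSet, partition: CREModulePartition,
                 n_network: int = 100, n_module: int = 100,
                 n_degree: int = 50) -> HubSets:
    """Network / module / degree hub CREs.

    Pair ranking is by weight with lexicographic tie-breaking, so the
    result is invariant to input edge order. An N beyond the available
    pairs takes everything with a warning.
    """
    import warnings

    if min(n_network, n_module, n_degree) < 1:
        raise ValueError("hub counts must be >= 1")
    pairs = sorted(zip(cre_edges.pairs, cre_edges.weights),
                   key=lambda pw: (-pw[1], pw[0]))
    if n_network > len(pairs):
        warnings.warn(f"n_network={n_network} exceeds {len(pairs)} pairs")
    network = sorted({c for (s, t), _ in pairs[:n_network] for c in (s, t)})

    module_hubs: set[str] = set()
    for m in sorted(set(partition.module_of.values())):
        members = set(partition.members(m))
        sub = [pw for pw in pairs
               if pw[0][0] in members and pw[0][1] in members]
        module_hubs |= {c for (s, t), _ in sub[:n_module] for c in (s, t)}

    degree: dict[str, float] = {}
    for (s, t), w in zip(cre_edges.pairs, cre_edges.weights):
        degree[s] = degree.get(s, 0.0) + float(w)
        degree[t] = degree.get(t, 0.0) + float(w)
    by_degree = sorted(degree, key=lambda c: (-degree[c], c))
    if n_degree > len(by_degree):
        warnings.warn(f"n_degree={n_degree} exceeds {len(by_degree)} CREs")
    return HubSets(network, sorted(module_hubs), by_degree[:n_degree])


def _overlaps_any(interval: tuple[str, int, int],
                  loci_by_chrom: dict[str, np.ndarray]) -> bool:
    chrom, start, end = interval
    arr = loci_by_chrom.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    return bool(((arr[:, 0] < end) & (arr[:, 1] > start)).any())


def _loci_index(loci: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in loci.groupby("chrom"):
        out[str(chrom)] = grp[["start", "end"]].to_numpy(int)
    return out


def locus_enrichment(hubs: list[str], loci: pd.DataFrame,
                     all_cres: NodeSet, n_perm: int = 1000,
                     seed: int = 0) -> dict:
    """Fold enrichment of hub CREs in a locus set, with permutation p.

    ``score = (hub overlap fraction) / (background overlap fraction)``;
    the empirical p-value draws ``n_perm`` seeded random CRE sets of the
    same size. A background without any overlap leaves the score
    undefined (reported as NaN).
    """
    idx = _loci_index(loci)
    overlap = np.array([_overlaps_any(all_cres.intervals[c], idx)
                        for c in all_cres.ids])
    bg_frac = overlap.mean()
    hub_set = set(hubs)
    missing = hub_set - set(all_cres.ids)
    if missing:
        raise KeyError(f"hub CREs missing from background: "
                       f"{sorted(missing)[:3]}")
    pos = {c: i for i, c in enumerate(all_cres.ids)}
    hub_idx = np.array([pos[c] for c in hubs], dtype=int)
    hub_frac = overlap[hub_idx].mean() if len(hub_idx) else 0.0
    if bg_frac == 0:
        return {"score": float("nan"), "p_value": float("nan"),
                "hub_fraction": float(hub_frac), "background_fraction": 0.0,
                "note": "no background CRE overlaps any locus"}
    score = hub_frac / bg_frac
    rng = np.random.default_rng(seed)
    n_hub = len(hub_idx)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(all_cres.ids), size=n_hub, replace=False)
        if overlap[draw].mean() >= hub_frac:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return {"score": float(score), "p_value": float(p),
            "hub_fraction": float(hub_frac),
            "background_fraction": float(bg_frac)}


def assign_hcg(hubs: list[str], cre_nodes: NodeSet,
               tss: pd.DataFrame, window: int = HCG_WINDOW) -> set[str]:
    """Genes with a TSS within the window around any hub CRE.

    The window is half-open ``[start - window, end + window)``, clipped
    at 0. ``tss`` needs gene, chrom and tss columns. A hub chromosome
    absent from the TSS table is reported.
    """
    tss_by_chrom = {str(c): grp for c, grp in tss.groupby("chrom")}
    out: set[str] = set()
    missing_chroms = set()
    for hub in hubs:
        chrom, start, end = cre_nodes.intervals[hub]
        grp = tss_by_chrom.get(chrom)
        if grp is None:
            missing_chroms.add(chrom)
            continue
        lo = max(0, start - window)
        hi = end + window
        sel = (grp["tss"] >= lo) & (grp["tss"] < hi)
        out |= set(grp.loc[sel, "gene"].astype(str))
    if missing_chroms:
        import warnings
        warnings.warn("no TSS entries for chromosome(s): "
                      + ", ".join(sorted(missing_chroms)))
    return out
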