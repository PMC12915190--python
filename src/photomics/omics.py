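"""Differential-expression screening and downstream set operations.

Per-feature fold change (raw ratio of group means) with a two-sample
Student's t-test (pooled variance by default, Welch optional),
Benjamini-Hochberg adjustment, threshold classification into
up/down/not-significant, screen-level count/percentage summaries, gene-set
intersection, hypergeometric enrichment and degree-based hub ranking.

Preset thresholds: proteomic FC > 1.1 / < 0.9, phosphoproteomic FC > 1.2 /
< 0.83 (both alpha 0.05 on raw p), transcript-style FC > 1.2 / < 0.83 with
BH-adjusted p < 0.01. The transcript preset is a generic FC + t-test
analogue of a count-model screen, not a reimplementation of one.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError

__all__ = [
    "AbundanceTable",
    "ScreenThresholds",
    "FeatureStat",
    "ScreenSummary",
    "GeneSet",
    "EnrichmentResult",
    "InteractionNetwork",
    "HubRanking",
    "PRESETS",
    "compute_feature_stats",
    "classify_features",
    "summarize_screen",
    "normalize_id",
    "intersect_gene_sets",
    "enrichment_test",
    "rank_hubs",
]

GROUPS = ("control", "treatment")


@dataclass
class AbundanceTable:
    """Features x samples matrix of positive normalized abundances."""

    feature_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    groups: dict[str, str]  # sample id -> "control" | "treatment"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("duplicate feature ids")
        if not np.all(self.values > 0):
            raise DataError("abundances must be strictly positive")
        for s in self.sample_ids:
            g = self.groups.get(s)
            if g not in GROUPS:
                raise DataError(f"sample {s!r} has invalid group {g!r}")
        for g in GROUPS:
            if sum(1 for s in self.sample_ids if self.groups[s] == g) < 2:
                raise DataError(f"need >= 2 samples in group {g!r}")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]
        return self.values[:, idx]


@dataclass
class ScreenThresholds:
    fc_up: float = 1.1
    fc_down: float = 0.9
    alpha: float = 0.05
    p_mode: Literal["raw", "bh_adjusted"] = "raw"

    def __post_init__(self) -> None:
        if not (self.fc_down < 1 < self.fc_up):
            raise ParameterError("thresholds must satisfy fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must be in (0, 1)")
        if self.p_mode not in ("raw", "bh_adjusted"):
            raise ParameterError(f"unknown p_mode {self.p_mode!r}")


#: Named threshold presets. The asymmetric printed bounds are kept literally.
PRESETS: dict[str, ScreenThresholds] = {
    "proteomic": ScreenThresholds(1.1, 0.9, 0.05, "raw"),
    "phospho": ScreenThresholds(1.2, 0.83, 0.05, "raw"),
    "transcript": ScreenThresholds(1.2, 0.83, 0.01, "bh_adjusted"),
}


@dataclass
class FeatureStat:
    feature_id: str
    mean_ctrl: float
    mean_trt: float
    fc: float
    p: float
    p_adj: float = float("nan")
    cls: str | None = None  # "up" | "down" | "ns" after classification
    flagged: bool = False  # degenerate variance, p forced


@dataclass
class ScreenSummary:
    n_identified: int
    n_up: int
    n_down: int
    n_total_dep: int
    pct_up: float
    pct_down: float


@dataclass
class GeneSet:
    name: str
    ids: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.ids = frozenset(self.ids)
        if not self.ids:
            raise DataError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    pathway: str
    k: int  # DEPs in pathway
    M: int  # detected features annotated to pathway
    n: int  # total DEPs
    N: int  # background size
    enrichment_factor: float  # k / M (0 and flagged when M == 0)
    p_hyper: float
    flagged: bool = False


@dataclass
class InteractionNetwork:
    """Simple undirected graph: unique unordered edges, no self-loops."""

    nodes: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen = set()
        canon = []
        for u, v in self.edges:
            if u == v:
                raise DataError(f"self-loop edge on node {u!r}")
            if u not in node_set or v not in node_set:
                raise DataError(f"edge ({u!r}, {v!r}) references unknown node")
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                raise DataError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            canon.append(key)
        self.edges = sorted(canon)
        self.nodes = sorted(node_set)

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass
class HubRanking:
    ranking: list[tuple[str, int]]  # (node, degree), degree desc, id asc


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def compute_feature_stats(
    table: AbundanceTable, welch: bool = False
) -> list[FeatureStat]:
    """Per-feature fold change and t-test p-values.

    fc = mean(treatment) / mean(control) on the raw (unlogged) scale; p from
    a two-sided two-sample t-test (pooled variance unless ``welch``);
    ``p_adj`` by Benjamini-Hochberg across all features. Features where both
    groups have zero variance get p = 1 (equal means, forced and flagged)
    or p = 0 (different constant means, flagged).
    """
    ctrl = table.group_columns("control")
    trt = table.group_columns("treatment")
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    fc = mean_t / mean_c

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sstats.ttest_ind(trt, ctrl, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = (ctrl.var(axis=1) == 0) & (trt.var(axis=1) == 0)
    p = np.where(degenerate, np.where(mean_c == mean_t, 1.0, 0.0), p)
    flagged = degenerate
    if np.isnan(p).any():
        raise DataError("t-test produced NaN p-values for non-degenerate rows")

    p_adj = multipletests(p, method="fdr_bh")[1]
    return [
        FeatureStat(
            feature_id=fid,
            mean_ctrl=float(mean_c[i]),
            mean_trt=float(mean_t[i]),
            fc=float(fc[i]),
            p=float(p[i]),
            p_adj=float(p_adj[i]),
            flagged=bool(flagged[i]),
        )
        for i, fid in enumerate(table.feature_ids)
    ]


def classify_features(
    stats: list[FeatureStat], thr: ScreenThresholds
) -> list[FeatureStat]:
    """Assign cls in place: up iff fc > fc_up and p* < alpha; down iff
    fc < fc_down and p* < alpha; else ns. p* = p or p_adj per ``p_mode``."""
    for st in stats:
        pstar = st.p if thr.p_mode == "raw" else st.p_adj
        if st.fc > thr.fc_up and pstar < thr.alpha:
            st.cls = "up"
        elif st.fc < thr.fc_down and pstar < thr.alpha:
            st.cls = "down"
        else:
            st.cls = "ns"
    return stats


def _pct(count: int, total: int) -> float:
    """100 * count / total, rounded half-away-from-zero to 2 decimals."""
    q = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def summarize_screen(
    stats: list[FeatureStat] | None = None,
    *,
    n_identified: int | None = None,
    n_up: int | None = None,
    n_down: int | None = None,
) -> ScreenSummary:
    """Screen-level counts and percentages.

    Either pass classified ``stats`` or explicit counts. In counts mode
    ``n_identified`` defaults to ``n_up + n_down`` when omitted. Percentages
    are of ``n_identified``, rounded half-away-from-zero to 2 decimals.
    """
    if stats is not None:
        if any(st.cls is None for st in stats):
            raise ParameterError("stats must be classified before summarizing")
        n_identified = len(stats)
        n_up = sum(st.cls == "up" for st in stats)
        n_down = sum(st.cls == "down" for st in stats)
    else:
        n_up = int(n_up or 0)
        n_down = int(n_down or 0)
        if n_identified is None:
            n_identified = n_up + n_down
    if n_identified <= 0:
        raise ParameterError("n_identified must be > 0")
    if n_up + n_down > n_identified:
        raise ParameterError("n_up + n_down exceeds n_identified")
    return ScreenSummary(
        n_identified=n_identified,
        n_up=n_up,
        n_down=n_down,
        n_total_dep=n_up + n_down,
        pct_up=_pct(n_up, n_identified),
        pct_down=_pct(n_down, n_identified),
    )


# ---------------------------------------------------------------------------
# gene sets / enrichment / hubs
# ---------------------------------------------------------------------------

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_id(identifier: str) -> str:
    """Case-fold and strip a numeric version suffix after the final dot."""
    return _VERSION_SUFFIX.sub("", identifier.strip()).casefold()


def intersect_gene_sets(
    query: Iterable[str], reference: GeneSet
) -> tuple[list[str], int]:
    """Exact set intersection after identifier normalization.

    Returns the sorted overlapping (normalized) ids and their count. An
    empty query yields an empty result, not an error.
    """
    q = {normalize_id(i) for i in query}
    r = {normalize_id(i) for i in reference.ids}
    overlap = sorted(q & r)
    return overlap, len(overlap)


def enrichment_test(
    dep_ids: Iterable[str], pathway: GeneSet, background: Iterable[str]
) -> EnrichmentResult:
    """Hypergeometric over-representation of a pathway among DEPs.

    k = |dep ∩ pathway ∩ background|, M = |pathway ∩ background|,
    n = |dep|, N = |background|; enrichment_factor = k / M (0 and flagged
    when M = 0); p_hyper = upper tail P(X >= k).
    """
    bg = {normalize_id(i) for i in background}
    dep = {normalize_id(i) for i in dep_ids}
    if not dep <= bg:
        missing = sorted(dep - bg)[:5]
        raise DataError(f"DEP ids not in background, e.g. {missing}")
    path = {normalize_id(i) for i in pathway.ids} & bg
    k = len(dep & path)
    M = len(path)
    n = len(dep)
    N = len(bg)
    if M == 0:
        return EnrichmentResult(pathway.name, 0, 0, n, N, 0.0, 1.0, flagged=True)
    p = float(sstats.hypergeom.sf(k - 1, N, M, n))
    return EnrichmentResult(
        pathway=pathway.name,
        k=k, M=M, n=n, N=N,
        enrichment_factor=k / M,
        p_hyper=min(max(p, 0.0), 1.0),
    )


def rank_hubs(network: InteractionNetwork, top_k: int = 9) -> HubRanking:
    """Rank nodes by degree descending, ties lexicographic; return top_k."""
    if top_k < 0:
        raise ParameterError("top_k must be >= 0")
    deg = network.degrees()
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds node count {len(ranked)}; truncating",
            stacklevel=2,
        )
        top_k = len(ranked)
    return HubRanking(ranking=ranked[:top_k])
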