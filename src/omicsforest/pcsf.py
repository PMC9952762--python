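"""Prize-collecting Steiner forest (PCSF) on the prized global network.

The solver selects a forest F from the network minimizing

    Obj(F) = beta * sum of prizes of EXCLUDED nodes
           + sum of edge costs inside F
           + omega * (number of trees in F)

which is the standard minimization form of "collect a maximum sum of
prizes while paying for connections and for opening each tree".  Nodes
selected with zero prize are Steiner nodes: non-quantified features kept
only to connect prized ones.

The heuristic reduces the forest problem to a rooted prize-collecting
Steiner tree by attaching a virtual root to every positive-prize node with
an edge of cost omega, grows Goemans–Williamson moats, strong-prunes the
resulting tree, and then polishes: local search (node addition, node
removal with tree splitting, two-hop addition, tree merging), re-spanning
the selected node set with its optimal forest (cost-sorted Kruskal on
reduced costs), and per-tree refitting to the best connected subtree.
Deleting the root leaves the forest; the surviving trees' count is kappa.

``brute_force_pcsf`` is an exact reference for tiny instances: it
enumerates every node subset and completes each with the optimal spanning
forest under reduced edge costs (cost − omega), which is the exact optimum
given the node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .network import InteractionNetwork

_EPS = 1e-12
_ROOT = "__pcsf_virtual_root__"

__all__ = ["PCSFConfig", "PCSFSolution", "pcsf_objective", "solve_pcsf", "brute_force_pcsf"]


@dataclass
class PCSFConfig:
    """Solver parameters: beta scales prizes, omega is the per-tree cost, mu
    the hub penalty (applied upstream on prizes), seed reserved for optional
    randomized tie-breaking (off by default; the solver is deterministic)."""

    beta: float = 1.0
    omega: float = 2.0
    mu: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass
class PCSFSolution:
    """A selected forest: nodes, edges, tree count kappa, objective value."""

    selected_nodes: frozenset
    selected_edges: frozenset  # of frozenset({u, v}) pairs
    kappa: int
    objective: float
    steiner_nodes: frozenset = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return len(self.selected_nodes)

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.selected_edges)


def _validate_forest(net: InteractionNetwork, nodes, edges) -> int:
    """Check forest validity inside the network; return tree count kappa."""
    nodes = set(nodes)
    norm_edges = set()
    for e in edges:
        u, v = tuple(e)
        if u not in nodes or v not in nodes:
            raise ValueError(f"edge {u!r}-{v!r} has an unselected endpoint")
        if not net.graph.has_edge(u, v):
            raise ValueError(f"edge {u!r}-{v!r} is not in the network")
        norm_edges.add(frozenset((u, v)))
    for v in nodes:
        if v not in net.graph:
            raise ValueError(f"selected node {v!r} is not in the network")
    if not nodes:
        return 0
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(tuple(e) for e in norm_edges)
    if g.number_of_edges() != len(norm_edges) or not nx.is_forest(g):
        raise ValueError("selected edges contain a cycle or a duplicate")
    return nx.number_connected_components(g)


def pcsf_objective(net: InteractionNetwork, nodes, edges, cfg: PCSFConfig) -> float:
    """Objective of a candidate forest; lower is better.  Validates the forest."""
    kappa = _validate_forest(net, nodes, edges)
    nodes = set(nodes)
    excluded = sum(net.prize(v) for v in net.graph.nodes if v not in nodes)
    edge_cost = sum(net.cost(*tuple(e)) for e in edges)
    return cfg.beta * excluded + edge_cost + cfg.omega * kappa


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        self.parent[rb] = ra
        return ra


class _Instance:
    """Precomputed dict view of the network for the solver's hot loops.

    Prizes are beta-scaled, so the objective is
    (total_bp − collected_bp) + edge costs + omega·kappa.
    """

    def __init__(self, net: InteractionNetwork, cfg: PCSFConfig):
        self.cfg = cfg
        self.nodes = net.nodes()
        self.bp = {v: cfg.beta * net.prize(v) for v in self.nodes}
        self.total_bp = sum(self.bp.values())
        self.cost = {}
        self.adj: dict[str, list[tuple[float, str]]] = {v: [] for v in self.nodes}
        for u, v in net.graph.edges:
            c = net.cost(u, v)
            key = (u, v) if u <= v else (v, u)
            self.cost[key] = c
            self.adj[u].append((c, v))
            self.adj[v].append((c, u))
        for v in self.nodes:
            self.adj[v].sort()
        self.sorted_edges = sorted((c, u, v) for (u, v), c in self.cost.items())

    def ecost(self, u, v) -> float:
        return self.cost[(u, v) if u <= v else (v, u)]

    def respan(self, sel: set) -> tuple[set, float]:
        """Optimal edge completion for a node set: Kruskal on edges with
        cost < omega (matroid greedy on reduced costs)."""
        if not sel:
            return set(), 0.0
        uf = _UnionFind(sel)
        edges: set = set()
        cost_sum = 0.0
        omega = self.cfg.omega
        for c, u, v in self.sorted_edges:
            if c >= omega:
                break
            if u in sel and v in sel and uf.find(u) != uf.find(v):
                uf.union(u, v)
                edges.add(frozenset((u, v)))
                cost_sum += c
        return edges, cost_sum

    def objective(self, sel: set, edges: set) -> float:
        cost_sum = sum(self.ecost(*tuple(e)) for e in edges)
        kappa = len(sel) - len(edges)
        return self.total_bp - sum(self.bp[v] for v in sel) + cost_sum + self.cfg.omega * kappa


# ---------------------------------------------------------------------------
# Goemans–Williamson moat growth on the rooted instance
# ---------------------------------------------------------------------------


def _gw_candidate_tree(inst: _Instance) -> nx.Graph:
    """Grow moats on the rooted instance; return the candidate tree that
    contains the virtual root (possibly the root alone)."""
    nodes = inst.nodes
    omega = inst.cfg.omega
    all_edges = [(u, v, c) for c, u, v in inst.sorted_edges]
    all_edges += [(_ROOT, v, omega) for v in nodes if inst.bp[v] > 0]

    uf = _UnionFind(nodes + [_ROOT])
    potential = dict(inst.bp)
    potential[_ROOT] = 0.0
    members = {v: [v] for v in nodes + [_ROOT]}
    has_root = {v: v == _ROOT for v in nodes + [_ROOT]}
    active = {v: potential[v] > _EPS and v != _ROOT for v in nodes + [_ROOT]}
    moat = {v: 0.0 for v in nodes + [_ROOT]}
    accepted: list[tuple[str, str]] = []
    n_active = sum(active.values())

    while n_active > 0:
        best_dt = None
        best_event = None  # ("edge", idx) or ("death", cluster)
        for idx, (u, v, c) in enumerate(all_edges):
            cu, cv = uf.find(u), uf.find(v)
            if cu == cv:
                continue
            rate = int(active[cu]) + int(active[cv])
            if rate == 0:
                continue
            dt = max(0.0, c - moat[u] - moat[v]) / rate
            if best_dt is None or dt < best_dt - _EPS:
                best_dt, best_event = dt, ("edge", idx)
        for c in nodes:
            if uf.find(c) == c and active[c]:
                dt = max(0.0, potential[c])
                if best_dt is None or dt < best_dt - _EPS:
                    best_dt, best_event = dt, ("death", c)
        if best_event is None:
            break
        if best_dt > 0:
            for c in {uf.find(x) for x in nodes}:
                if active[c]:
                    potential[c] -= best_dt
                    for v in members[c]:
                        moat[v] += best_dt
        kind, payload = best_event
        if kind == "edge":
            u, v, c = all_edges[payload]
            cu, cv = uf.find(u), uf.find(v)
            if cu != cv:
                accepted.append((u, v))
                was_active = int(active[cu]) + int(active[cv])
                new = uf.union(cu, cv)
                other = cv if new == cu else cu
                potential[new] = potential[cu] + potential[cv]
                members[new] = members[cu] + members[cv]
                has_root[new] = has_root[cu] or has_root[cv]
                active[new] = (not has_root[new]) and potential[new] > _EPS
                active[other] = False
                n_active += int(active[new]) - was_active
        else:
            active[payload] = False
            n_active -= 1

    g = nx.Graph()
    g.add_nodes_from(nodes + [_ROOT])
    g.add_edges_from(accepted)
    comp = nx.node_connected_component(g, _ROOT)
    return g.subgraph(comp).copy()


def _mst_candidate_tree(inst: _Instance) -> nx.Graph:
    """Alternative candidate: minimum spanning tree of the rooted graph
    (virtual root joined to every positive-prize node at cost omega),
    restricted to the root's component."""
    g = nx.Graph()
    g.add_nodes_from(inst.nodes)
    g.add_node(_ROOT)
    for c, u, v in inst.sorted_edges:
        g.add_edge(u, v, weight=c)
    for v in inst.nodes:
        if inst.bp[v] > 0:
            g.add_edge(_ROOT, v, weight=inst.cfg.omega)
    comp = nx.node_connected_component(g, _ROOT)
    return nx.minimum_spanning_tree(g.subgraph(comp), algorithm="kruskal")


def _strong_prune(inst: _Instance, tree: nx.Graph) -> set:
    """Optimal subtree selection of the rooted candidate tree.

    Net worth of a subtree rooted at v is beta*prize(v) plus every child
    subtree worth more than its connecting edge; children at the virtual
    root must beat the tree-opening cost omega.  Returns the selected
    node set (edges are recovered later by re-spanning)."""
    if _ROOT not in tree or tree.number_of_nodes() == 1:
        return set()
    order = list(nx.dfs_postorder_nodes(tree, _ROOT))
    parent = nx.dfs_predecessors(tree, _ROOT)
    children: dict = {v: [] for v in tree.nodes}
    for v, p in parent.items():
        children[p].append(v)
    worth = {}
    keep_child: dict = {v: [] for v in tree.nodes}
    for v in order:
        if v == _ROOT:
            continue
        w = inst.bp[v]
        for c in children[v]:
            ec = inst.ecost(v, c)
            if worth[c] > ec + _EPS:
                w += worth[c] - ec
                keep_child[v].append(c)
        worth[v] = w
    for c in children[_ROOT]:
        if worth[c] > inst.cfg.omega + _EPS:
            keep_child[_ROOT].append(c)
    sel: set = set(keep_child[_ROOT])
    stack = list(keep_child[_ROOT])
    while stack:
        v = stack.pop()
        for c in keep_child[v]:
            sel.add(c)
            stack.append(c)
    return sel


# ---------------------------------------------------------------------------
# polish: local search, per-tree refit, drop-with-respan
# ---------------------------------------------------------------------------


def _forest_components(sel: set, edges: set) -> dict:
    uf = _UnionFind(sel)
    for e in edges:
        u, v = tuple(e)
        uf.union(u, v)
    return {v: uf.find(v) for v in sel}


def _local_search(inst: _Instance, sel: set, edges: set) -> tuple[set, set]:
    """Best-improvement moves on (node set, forest edges); deterministic."""
    cfg = inst.cfg
    sel = set(sel)
    edges = set(edges)
    for _ in range(4 * len(inst.nodes) + 20):
        comp = _forest_components(sel, edges)
        fadj: dict = {v: [] for v in sel}
        for e in edges:
            u, v = tuple(e)
            fadj[u].append(v)
            fadj[v].append(u)
        best_delta = -1e-9
        best_move = None
        for v in inst.nodes:
            if v in sel:
                # drop: a degree-d node's removal splits its tree into d trees
                inc = fadj[v]
                delta = (
                    inst.bp[v]
                    - sum(inst.ecost(v, u) for u in inc)
                    + cfg.omega * (len(inc) - 1)
                )
                if delta < best_delta:
                    best_delta, best_move = delta, ("drop", v, None)
            else:
                # add: attach via the cheapest edge into the forest, or open a tree
                attach, attach_cost = None, cfg.omega
                for c, u in inst.adj[v]:
                    if c >= attach_cost:
                        break
                    if u in sel:
                        attach, attach_cost = u, c
                        break
                delta = attach_cost - inst.bp[v]
                if delta < best_delta:
                    best_delta, best_move = delta, ("add", v, attach)
        # two-hop addition through an unselected intermediate
        if sel:
            for w in inst.nodes:
                if w in sel:
                    continue
                w_attach = None
                for c, u in inst.adj[w]:
                    if u in sel:
                        w_attach = c
                        break
                if w_attach is None:
                    continue
                for c, v in inst.adj[w]:
                    if v in sel:
                        continue
                    delta = w_attach + c - inst.bp[w] - inst.bp[v]
                    if delta < best_delta:
                        best_delta, best_move = delta, ("add2", w, v)
        # merge two trees through an existing edge (saves one omega)
        for c, u, v in inst.sorted_edges:
            if c >= cfg.omega:
                break
            if u in sel and v in sel and comp[u] != comp[v]:
                delta = c - cfg.omega
                if delta < best_delta:
                    best_delta, best_move = delta, ("merge", u, v)
        if best_move is None:
            break
        kind, a, b = best_move
        if kind == "add":
            sel.add(a)
            if b is not None:
                edges.add(frozenset((a, b)))
        elif kind == "add2":
            w_attach = next(u for c, u in inst.adj[a] if u in sel)
            sel.add(a)
            edges.add(frozenset((a, w_attach)))
            sel.add(b)
            edges.add(frozenset((a, b)))
        elif kind == "drop":
            sel.discard(a)
            edges = {e for e in edges if a not in e}
        else:
            edges.add(frozenset((a, b)))
    return sel, edges


def _refit_trees(inst: _Instance, sel: set, edges: set) -> set:
    """Replace every tree by its best connected subtree (rerooting DP, O(n)
    per tree); trees whose best subtree is worth <= omega are dropped."""
    comp = _forest_components(sel, edges)
    fadj: dict = {v: [] for v in sel}
    for e in edges:
        u, v = tuple(e)
        c = inst.ecost(u, v)
        fadj[u].append((v, c))
        fadj[v].append((u, c))
    by_comp: dict = {}
    for v in sel:
        by_comp.setdefault(comp[v], []).append(v)
    out: set = set()
    for root, nodes_in in sorted(by_comp.items()):
        r0 = min(nodes_in)
        # iterative postorder
        parent = {r0: None}
        pcost = {r0: 0.0}
        order = []
        stack = [r0]
        while stack:
            v = stack.pop()
            order.append(v)
            for u, c in fadj[v]:
                if u not in parent:
                    parent[u] = v
                    pcost[u] = c
                    stack.append(u)
        down = {}
        for v in reversed(order):
            w = inst.bp[v]
            for u, c in fadj[v]:
                if parent.get(u) == v:
                    w += max(0.0, down[u] - c)
            down[v] = w
        # reroot: up[v] = best worth reachable through the parent side
        up = {r0: 0.0}
        for v in order:
            for u, c in fadj[v]:
                if parent.get(u) == v:
                    through_parent = up[v] + down[v] - max(0.0, down[u] - c)
                    up[u] = max(0.0, through_parent - c)
        best_r = max(nodes_in, key=lambda v: (down[v] + up[v], v))
        best_worth = down[best_r] + up[best_r]
        if best_worth <= inst.cfg.omega + _EPS:
            continue  # tree not worth opening
        # strong prune rooted at the best root
        parent = {best_r: None}
        order = []
        stack = [best_r]
        seen = {best_r}
        while stack:
            v = stack.pop()
            order.append(v)
            for u, c in fadj[v]:
                if u not in seen:
                    seen.add(u)
                    parent[u] = v
                    stack.append(u)
        worth = {}
        keep: dict = {v: [] for v in nodes_in}
        for v in reversed(order):
            w = inst.bp[v]
            for u, c in fadj[v]:
                if parent.get(u) == v:
                    if worth[u] > c + _EPS:
                        w += worth[u] - c
                        keep[v].append(u)
            worth[v] = w
        kept = {best_r}
        stack = [best_r]
        while stack:
            v = stack.pop()
            for u in keep[v]:
                kept.add(u)
                stack.append(u)
        out |= kept
    return out


def solve_pcsf(net: InteractionNetwork, cfg: PCSFConfig) -> PCSFSolution:
    """Heuristic PCSF: best of GW moat growth and rooted-MST candidates,
    each strong-pruned and polished.

    Deterministic for a given network (all iteration orders are sorted).
    A network with zero total adjusted prize yields the empty forest.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    if net.total_prize() <= 0:
        return PCSFSolution(frozenset(), frozenset(), 0, pcsf_objective(net, set(), set(), cfg))
    inst = _Instance(net, cfg)
    small = net.n_nodes <= 250  # exhaustive drop-with-respan only at small scale

    def polish(sel: set) -> tuple[set, set, float]:
        edges, _ = inst.respan(sel)
        prev = float("inf")
        for _ in range(10):
            sel, edges = _local_search(inst, sel, edges)
            sel = _refit_trees(inst, sel, edges)
            edges, _ = inst.respan(sel)
            cur = inst.objective(sel, edges)
            if small:
                # removing one node (or a pair of low-prize connectors) and
                # re-spanning escapes optima where connector nodes force a
                # costly topology
                improved = False
                for v in sorted(sel):
                    cand = sel - {v}
                    cand_edges, _ = inst.respan(cand)
                    cand_obj = inst.objective(cand, cand_edges)
                    if cand_obj < cur - _EPS:
                        sel, edges, cur = cand, cand_edges, cand_obj
                        improved = True
                        break
                if not improved and len(sel) <= 60:
                    ordered = sorted(sel)
                    for i, u in enumerate(ordered):
                        for v in ordered[i + 1:]:
                            cand = sel - {u, v}
                            cand_edges, _ = inst.respan(cand)
                            cand_obj = inst.objective(cand, cand_edges)
                            if cand_obj < cur - _EPS:
                                sel, edges, cur = cand, cand_edges, cand_obj
                                improved = True
                                break
                        if improved:
                            break
            if cur >= prev - _EPS:
                break
            prev = cur
        return sel, edges, inst.objective(sel, edges)

    best_sel: set = set()
    best_edges: set = set()
    best_obj = inst.objective(set(), set())
    for tree in (_gw_candidate_tree(inst), _mst_candidate_tree(inst)):
        sel, edges, obj = polish(_strong_prune(inst, tree))
        if obj < best_obj - _EPS:
            best_sel, best_edges, best_obj = sel, edges, obj
    obj = pcsf_objective(net, best_sel, best_edges, cfg)  # validates the forest
    kappa = _validate_forest(net, best_sel, best_edges)
    steiner = frozenset(v for v in best_sel if net.prize(v) == 0)
    return PCSFSolution(frozenset(best_sel), frozenset(best_edges), kappa, obj, steiner)


def brute_force_pcsf(net: InteractionNetwork, cfg: PCSFConfig) -> PCSFSolution:
    """Exact optimum by exhaustive enumeration; refuses instances > 15 nodes.

    For a fixed node subset S the optimal completion is the spanning forest
    minimizing sum(cost − omega) over acyclic edge sets inside S (matroid
    greedy: take cost-sorted edges with cost < omega that join distinct
    components).  Ties break toward fewer nodes, then lexicographic ids.
    """
    nodes = net.nodes()
    n = len(nodes)
    if n > 15:
        raise ValueError(f"brute force limited to 15 nodes, got {n}")
    edge_list = sorted(
        ((net.cost(u, v), *sorted((u, v))) for u, v in net.graph.edges),
        key=lambda t: (t[0], t[1], t[2]),
    )
    total_prize = net.total_prize()
    best = None  # (objective, |S|, sorted node tuple, S, edges)
    for mask in range(1 << n):
        sel = [nodes[i] for i in range(n) if mask >> i & 1]
        sel_set = set(sel)
        uf = _UnionFind(sel) if sel else None
        chosen = []
        cost_sum = 0.0
        for c, u, v in edge_list:
            if c >= cfg.omega:
                break
            if u in sel_set and v in sel_set and uf.find(u) != uf.find(v):
                uf.union(u, v)
                chosen.append(frozenset((u, v)))
                cost_sum += c
        kappa = len(sel) - len(chosen)
        obj = (
            cfg.beta * (total_prize - sum(net.prize(v) for v in sel))
            + cost_sum
            + cfg.omega * kappa
        )
        key = (len(sel), tuple(sorted(sel)))
        if best is None or obj < best[0] - _EPS or (
            abs(obj - best[0]) <= _EPS and key < (best[1], best[2])
        ):
            best = (obj, len(sel), tuple(sorted(sel)), sel_set, set(chosen))
    obj, _, _, sel_set, chosen = best
    steiner = frozenset(v for v in sel_set if net.prize(v) == 0)
    return PCSFSolution(frozenset(sel_set), frozenset(chosen), len(sel_set) - len(chosen), obj, steiner)
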