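"""Reconstruction of whole stress-fiber centerlines from fragments.

Fragments produced by junction removal are re-joined tip-to-tip under
four geometric criteria evaluated between a *base* terminus ``i`` and a
*candidate* terminus ``j`` (``phi`` denotes a propagation direction,
``varphi`` the direction of the gap vector from i to j):

1. **similarity** — the angle between ``phi_i`` and the *reverse* of
   ``phi_j`` is at most ``phi_max`` (the two tips face each other);
2. **proximity** — the gap ``|d_ij|`` is at most ``d_max``;
3. **continuity** — the angle between ``phi_i`` and ``varphi_ij`` is at
   most ``psi_max`` (the partner lies ahead of the base tip);
4. **inner fragment** — if a third fragment ``m`` inside the search fan
   could itself bridge ``i`` and ``j`` (its near tips satisfy similarity
   and continuity toward both), the direct ``i``-``j`` connection is
   rejected in favor of pairing through the bridge.

When several candidates survive, a normalized cost ranks them::

    C = w_angle * d_theta / max_k d_theta_k + w_gap * d_theta_gap / max_k d_theta_gap_k

(0/0 taken as 0); the lowest cost wins.  Pairing is greedy: base termini
are visited in descending fragment length, accepted pairings are final,
and passes repeat until none is added.  Chains of paired fragments form
the fiber traces; unpaired termini are the fiber ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import angle_between, direction_deg
from .segment import FilamentFragment

__all__ = [
    "PairingParams",
    "Terminus",
    "PairEvaluation",
    "FiberTrace",
    "evaluate_pair",
    "find_candidates",
    "bridge_eligible",
    "score_candidates",
    "reconstruct",
    "traces_to_csv",
]


@dataclass
class PairingParams:
    """Geometric bounds and cost weights for terminus pairing.

    phi_max : similarity bound, degrees.
    d_max : proximity bound (maximum gap length), px; 16 px is ~1.7 um
        at 108 nm/px.
    psi_max : continuity bound, degrees.
    search_radius : fan radius, px (defaults to ``d_max``).
    search_angle : fan half-sweep around the propagation direction, degrees.
    c_angle_weight / c_gap_weight : cost weights for the similarity and
        continuity mismatches.
    """

    phi_max: float = 30.0
    d_max: float = 16.0
    psi_max: float = 30.0
    search_radius: float | None = None
    search_angle: float = 30.0
    c_angle_weight: float = 0.5
    c_gap_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.search_radius is None:
            self.search_radius = self.d_max
        if min(self.phi_max, self.d_max, self.psi_max,
               self.search_radius, self.search_angle) <= 0:
            raise ValueError("all bounds must be positive")
        if self.c_angle_weight < 0 or self.c_gap_weight < 0 \
                or self.c_angle_weight + self.c_gap_weight == 0:
            raise ValueError("weights must be >= 0 and not both zero")


@dataclass
class Terminus:
    """One endpoint of a fragment with its propagation direction ``phi``."""

    fragment_id: int
    which_end: str  # "A" or "B"
    position: tuple[float, float]
    phi: float
    paired_with: "Terminus | None" = None

    @property
    def key(self) -> tuple[int, str]:
        return (self.fragment_id, self.which_end)


@dataclass
class PairEvaluation:
    """Outcome of the three pairwise criteria for a terminus pair."""

    d_ij: float
    varphi_ij: float
    delta_theta: float
    delta_theta_gap: float
    passes_similarity: bool
    passes_proximity: bool
    passes_continuity: bool
    bridge: int | None = None
    cost: float | None = None

    @property
    def passes(self) -> bool:
        return (self.passes_similarity and self.passes_proximity
                and self.passes_continuity)


@dataclass
class FiberTrace:
    """An ordered chain of fragments forming one reconstructed fiber."""

    id: int
    fragment_ids: list[int]
    pixels: np.ndarray

    @property
    def length_px(self) -> float:
        d = np.diff(self.pixels.astype(float), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def __len__(self) -> int:
        return len(self.pixels)


def fragment_termini(fragments: list[FilamentFragment]) -> list[Terminus]:
    """Both termini of every fragment, A before B."""
    out = []
    for f in fragments:
        out.append(Terminus(f.id, "A", tuple(map(float, f.terminus_a)),
                            f.direction_a))
        out.append(Terminus(f.id, "B", tuple(map(float, f.terminus_b)),
                            f.direction_b))
    return out


def evaluate_pair(t_i: Terminus, t_j: Terminus,
                  params: PairingParams) -> PairEvaluation:
    """Evaluate similarity, proximity and continuity for a terminus pair."""
    gap = (t_j.position[0] - t_i.position[0], t_j.position[1] - t_i.position[1])
    d_ij = float(np.hypot(*gap))
    varphi = direction_deg(*gap) if d_ij > 0 else t_i.phi
    delta_theta = angle_between(t_i.phi, t_j.phi + 180.0)
    delta_theta_gap = angle_between(t_i.phi, varphi)
    return PairEvaluation(
        d_ij=d_ij,
        varphi_ij=varphi,
        delta_theta=delta_theta,
        delta_theta_gap=delta_theta_gap,
        passes_similarity=delta_theta <= params.phi_max,
        passes_proximity=d_ij <= params.d_max,
        passes_continuity=delta_theta_gap <= params.psi_max,
    )


def find_candidates(base: Terminus, all_termini: list[Terminus],
                    params: PairingParams) -> list[Terminus]:
    """Unpaired termini of other fragments inside the base's search fan."""
    out = []
    for t in all_termini:
        if t.fragment_id == base.fragment_id or t.paired_with is not None:
            continue
        gap = (t.position[0] - base.position[0], t.position[1] - base.position[1])
        d = float(np.hypot(*gap))
        if d == 0.0 or d > params.search_radius:
            continue
        if angle_between(base.phi, direction_deg(*gap)) <= params.search_angle:
            out.append(t)
    return out


def _near_tip(fragment_termini_m: tuple[Terminus, Terminus],
              to: Terminus) -> Terminus:
    """The terminus of fragment m closest to the terminus ``to``."""
    a, b = fragment_termini_m
    da = np.hypot(a.position[0] - to.position[0], a.position[1] - to.position[1])
    db = np.hypot(b.position[0] - to.position[0], b.position[1] - to.position[1])
    return a if da <= db else b


def bridge_eligible(t_i: Terminus, t_j: Terminus,
                    m_termini: tuple[Terminus, Terminus],
                    params: PairingParams) -> bool:
    """Can fragment m (given by its two termini) bridge the pair i-j?

    Tip *a* of m is the one nearest i, tip *b* the one nearest j; the
    bridge is eligible when similarity and continuity hold between i and a
    and between j and b (with the same ``phi_max``/``psi_max`` bounds).
    """
    t_a = _near_tip(m_termini, t_i)
    t_b = _near_tip(m_termini, t_j)
    ev_ia = evaluate_pair(t_i, t_a, params)
    if not (ev_ia.passes_similarity and ev_ia.passes_continuity):
        return False
    ev_jb = evaluate_pair(t_j, t_b, params)
    return ev_jb.passes_similarity and ev_jb.passes_continuity


def score_candidates(evals: list[PairEvaluation],
                     params: PairingParams) -> list[float]:
    """Normalized pairing costs (lower is better); 0/0 terms are 0."""
    if not evals:
        return []
    max_theta = max(e.delta_theta for e in evals)
    max_gap = max(e.delta_theta_gap for e in evals)
    costs = []
    for e in evals:
        c = 0.0
        if max_theta > 0:
            c += params.c_angle_weight * e.delta_theta / max_theta
        if max_gap > 0:
            c += params.c_gap_weight * e.delta_theta_gap / max_gap
        e.cost = c
        costs.append(c)
    return costs


def _accept_pairings(fragments: list[FilamentFragment],
                     params: PairingParams) -> tuple[list[Terminus], list]:
    """Greedy pairing loop; returns termini and accepted links
    (terminus, terminus, cost)."""
    termini = fragment_termini(fragments)
    by_key = {t.key: t for t in termini}
    frag_termini = {f.id: (by_key[(f.id, "A")], by_key[(f.id, "B")])
                    for f in fragments}
    lengths = {f.id: len(f) for f in fragments}
    order = sorted(termini,
                   key=lambda t: (-lengths[t.fragment_id], t.fragment_id,
                                  t.which_end))
    links = []
    while True:
        added = False
        for base in order:
            if base.paired_with is not None:
                continue
            cands = find_candidates(base, termini, params)
            evals = [(t, evaluate_pair(base, t, params)) for t in cands]
            evals = [(t, e) for t, e in evals if e.passes]
            if not evals:
                continue
            # inner-fragment criterion: fragments with an unpaired tip in
            # the fan may veto a direct connection they could bridge
            fan_frag_ids = {t.fragment_id for t in cands}
            kept = []
            for t, e in evals:
                vetoed = False
                for mid in fan_frag_ids:
                    if mid in (base.fragment_id, t.fragment_id):
                        continue
                    if bridge_eligible(base, t, frag_termini[mid], params):
                        e.bridge = mid
                        vetoed = True
                        break
                if not vetoed:
                    kept.append((t, e))
            if not kept:
                continue
            score_candidates([e for _, e in kept], params)
            kept.sort(key=lambda te: (te[1].cost, te[1].d_ij,
                                      te[0].fragment_id))
            best_t, best_e = kept[0]
            base.paired_with = best_t
            best_t.paired_with = base
            links.append((base, best_t, best_e.cost))
            added = True
        if not added:
            return termini, links


def _assemble_traces(fragments: list[FilamentFragment],
                     links: list) -> list[FiberTrace]:
    frag_by_id = {f.id: f for f in fragments}
    # adjacency: (fragment_id, end) -> (fragment_id, end) for accepted links
    adj: dict[tuple[int, str], tuple[int, str]] = {}
    link_cost: dict[frozenset, float] = {}
    for a, b, cost in links:
        adj[a.key] = b.key
        adj[b.key] = a.key
        link_cost[frozenset((a.key, b.key))] = cost

    traces: list[FiberTrace] = []
    visited: set[int] = set()

    def other_end(end: str) -> str:
        return "B" if end == "A" else "A"

    def walk(fid: int, entry_end: str) -> list[tuple[int, str]]:
        """Follow links starting at fragment ``fid`` entered at
        ``entry_end``; stops when an end is unlinked or a cycle closes."""
        chain = []
        cur = (fid, entry_end)
        while True:
            f, e = cur
            chain.append(cur)
            out = (f, other_end(e))
            nxt = adj.get(out)
            if nxt is None or nxt[0] in {c[0] for c in chain}:
                return chain
            cur = (nxt[0], nxt[1])

    # detect pure cycles and cut them at the costliest link
    for f in fragments:
        if f.id in visited:
            continue
        # find a free end to start from
        start = None
        for end in ("A", "B"):
            if (f.id, end) not in adj:
                start = (f.id, end)
                break
        if start is None:
            # fragment is linked at both ends: may be mid-chain (skip; it
            # will be reached from a free end) or part of a cycle
            continue
        chain = walk(*start)
        visited.update(c[0] for c in chain)
        traces.append(_chain_to_trace(chain, frag_by_id, len(traces)))

    # remaining fragments are in cycles
    for f in fragments:
        if f.id in visited:
            continue
        chain = walk(f.id, "A")
        cycle_ids = [c[0] for c in chain]
        # cut the costliest link within the cycle
        worst = max(
            (k for k in link_cost
             if all(fid in cycle_ids for fid, _ in k)),
            key=lambda k: link_cost[k], default=None)
        if worst is not None:
            warnings.warn("cyclic pairing chain broken at highest-cost link",
                          stacklevel=2)
            (f1, e1), (f2, e2) = sorted(worst)
            adj.pop((f1, e1), None)
            adj.pop((f2, e2), None)
            chain = walk(f1, e1)
        visited.update(c[0] for c in chain)
        traces.append(_chain_to_trace(chain, frag_by_id, len(traces)))
    return traces


def _chain_to_trace(chain: list[tuple[int, str]],
                    frag_by_id: dict[int, FilamentFragment],
                    trace_id: int) -> FiberTrace:
    pieces = []
    for fid, entry_end in chain:
        px = frag_by_id[fid].pixels
        pieces.append(px if entry_end == "A" else px[::-1])
    return FiberTrace(
        id=trace_id,
        fragment_ids=[fid for fid, _ in chain],
        pixels=np.vstack(pieces),
    )


def reconstruct(fragments: list[FilamentFragment],
                params: PairingParams | None = None) -> list[FiberTrace]:
    """Pair fragment termini and assemble fiber traces.

    Every fragment ends up in exactly one trace; fragments whose termini
    never pair become single-fragment traces.
    """
    params = params or PairingParams()
    if not fragments:
        return []
    termini, links = _accept_pairings(fragments, params)
    return _assemble_traces(fragments, links)


def traces_to_csv(traces: list[FiberTrace]) -> pd.DataFrame:
    rows = [(t.id, i, int(r), int(c))
            for t in traces for i, (r, c) in enumerate(t.pixels)]
    return pd.DataFrame(rows, columns=["fiber_id", "point_index", "row", "col"])
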