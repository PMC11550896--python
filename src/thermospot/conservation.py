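"""Cross-session spot conservation under a spatial tolerance.

A confirmed spot is considered conserved if any confirmed spot of the same
participant in a *different* session lies strictly less than a threshold
distance away (default 6 px = 2 mm at 0.33 mm/px, twice the stimulator wire
diameter). Matching is by distance threshold only — no one-to-one
assignment — so a spot may match several partners; matched spots form
connected components ("chains") on the match graph.

Two counting conventions are reported side by side because "n spots were
reidentified" is ambiguous about whether both members of a matched pair
count:

* ``component`` (default): every confirmed spot in a cross-session-matched
  component counts once, so an isolated pair contributes 2;
* ``reidentification``: only spots matched to an earlier session count, so
  an isolated pair contributes 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .spot_model import SpotRecord, SpotTable

__all__ = ["MatchPair", "ConservationResult", "match_spots", "category_agreement"]


@dataclass(frozen=True)
class MatchPair:
    """A cross-session pair of confirmed spots closer than the threshold."""

    spot_a: SpotRecord  # earlier session
    spot_b: SpotRecord  # later session
    distance_px: float

    @property
    def same_category(self) -> bool:
        return self.spot_a.category == self.spot_b.category


@dataclass
class ConservationResult:
    pairs: list[MatchPair]
    conserved_spots: list[SpotRecord]
    n_conserved: int
    n_conserved_component: int
    n_conserved_reidentified: int
    n_confirmed: int
    conservation_rate: float  # percent of confirmed spots
    max_chain_length: int  # size of the largest matched component
    max_sessions_spanned: int  # distinct sessions in the largest-spanning component
    n_category_agree: int
    threshold_px: float
    convention: str


def _spot_key(rec: SpotRecord) -> tuple:
    return (rec.participant_id, rec.session_id, rec.x_px, rec.y_px)


def match_spots(
    table: SpotTable,
    threshold_px: float = 6.0,
    convention: str = "component",
) -> ConservationResult:
    """Enumerate all cross-session matches strictly closer than the threshold.

    Only confirmed spots participate. A single-session table yields an empty
    result, not an error.
    """
    if threshold_px <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_px}")
    if convention not in ("component", "reidentification"):
        raise ValueError(f"unknown counting convention {convention!r}")

    confirmed = table.confirmed().records
    graph = nx.Graph()
    for rec in confirmed:
        graph.add_node(_spot_key(rec), rec=rec)

    pairs: list[MatchPair] = []
    by_participant: dict[str, list[SpotRecord]] = {}
    for rec in confirmed:
        by_participant.setdefault(rec.participant_id, []).append(rec)

    for recs in by_participant.values():
        pts = np.array([(r.x_px, r.y_px) for r in recs])
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if recs[i].session_id == recs[j].session_id:
                    continue
                d = float(np.hypot(*(pts[i] - pts[j])))
                if d < threshold_px:
                    a, b = recs[i], recs[j]
                    if a.session_id > b.session_id:
                        a, b = b, a
                    pairs.append(MatchPair(a, b, d))
                    graph.add_edge(_spot_key(recs[i]), _spot_key(recs[j]))

    components = [c for c in nx.connected_components(graph) if len(c) > 1]
    # every edge is cross-session, so any component of size > 1 spans >= 2 sessions
    conserved_component = [
        graph.nodes[k]["rec"] for c in components for k in sorted(c)
    ]
    reidentified = sorted(
        {
            _spot_key(p.spot_b)
            for p in pairs
        }
    )
    n_component = len(conserved_component)
    n_reident = len(reidentified)
    conserved = (
        conserved_component
        if convention == "component"
        else [graph.nodes[k]["rec"] for k in reidentified]
    )
    n_conserved = len(conserved)
    n_confirmed = len(confirmed)

    max_chain = max((len(c) for c in components), default=0)
    max_sessions = max(
        (len({graph.nodes[k]["rec"].session_id for k in c}) for c in components),
        default=0,
    )

    result = ConservationResult(
        pairs=pairs,
        conserved_spots=conserved,
        n_conserved=n_conserved,
        n_conserved_component=n_component,
        n_conserved_reidentified=n_reident,
        n_confirmed=n_confirmed,
        conservation_rate=100.0 * n_conserved / n_confirmed if n_confirmed else 0.0,
        max_chain_length=max_chain,
        max_sessions_spanned=max_sessions,
        n_category_agree=0,
        threshold_px=threshold_px,
        convention=convention,
    )
    result.n_category_agree = category_agreement(result)
    return result


def category_agreement(result: ConservationResult) -> int:
    """Count conserved spots whose whole chain shares a single category.

    Agreement is component-wide: every spot linked (directly or through
    intermediates) must carry the same category, so a cold-cold-warm chain
    contributes 0 for all three members.
    """
    graph = nx.Graph()
    for p in result.pairs:
        graph.add_edge(_spot_key(p.spot_a), _spot_key(p.spot_b))
        graph.nodes[_spot_key(p.spot_a)]["rec"] = p.spot_a
        graph.nodes[_spot_key(p.spot_b)]["rec"] = p.spot_b

    agree_keys: set[tuple] = set()
    for comp in nx.connected_components(graph):
        cats = {graph.nodes[k]["rec"].category for k in comp}
        if len(cats) == 1:
            agree_keys |= comp

    return sum(1 for rec in result.conserved_spots if _spot_key(rec) in agree_keys)
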