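"""Meal-versus-habitual network comparison.

Edges are matched *direction-specifically*: an undirected food-group pair
counts as shared only when it appears in both networks with the same
partial-correlation sign. Only edges inside identified networks (connected
components of three or more groups) are compared; a meal with several such
components has them pooled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .copula import PartialCorrelationNetwork

EdgeKey = tuple[str, str, int]  # (u, v, sign) with u < v

__all__ = [
    "EdgeKey",
    "network_edge_keys",
    "edge_overlap",
    "habitual_unique",
    "sign_discordance",
    "strength_comparison",
    "OverlapReport",
    "compare_networks",
]


def network_edge_keys(net: PartialCorrelationNetwork,
                      networks_only: bool = True,
                      sign_specific: bool = True) -> frozenset[EdgeKey]:
    """Direction-specific edge keys of a network.

    With ``networks_only`` only edges whose endpoints lie in a component of
    >= 3 groups are counted; with ``sign_specific`` off the sign slot is 0.
    """
    keep = net.network_nodes() if networks_only else None
    keys = set()
    for e in net.edges:
        if keep is not None and (e.u not in keep or e.v not in keep):
            continue
        u, v = (e.u, e.v) if e.u <= e.v else (e.v, e.u)
        sign = (1 if e.pcor > 0 else -1) if sign_specific else 0
        keys.add((u, v, sign))
    return frozenset(keys)


def edge_overlap(meal_net: PartialCorrelationNetwork,
                 habitual_net: PartialCorrelationNetwork,
                 sign_specific: bool = True) -> tuple[int, int, float | None]:
    """(matched, total, percentage) of meal edges present in the habitual net.

    Percentage is rounded to one decimal; an empty meal network yields
    (0, 0, None) — explicitly "empty", not 0%.
    """
    if set(meal_net.nodes) != set(habitual_net.nodes):
        raise ValueError("networks must share the same node label set")
    meal = network_edge_keys(meal_net, sign_specific=sign_specific)
    hab = network_edge_keys(habitual_net, sign_specific=sign_specific)
    total = len(meal)
    if total == 0:
        return 0, 0, None
    matched = len(meal & hab)
    return matched, total, round(100.0 * matched / total, 1)


def habitual_unique(habitual_net: PartialCorrelationNetwork,
                    meal_nets: Sequence[PartialCorrelationNetwork],
                    sign_specific: bool = True) -> float | None:
    """Percentage of habitual edges absent from every meal network."""
    hab = network_edge_keys(habitual_net, sign_specific=sign_specific)
    if not hab:
        return None
    union: set[EdgeKey] = set()
    for net in meal_nets:
        union |= network_edge_keys(net, sign_specific=sign_specific)
    unique = len(hab - union)
    return round(100.0 * unique / len(hab), 1)


def sign_discordance(meal_net: PartialCorrelationNetwork,
                     habitual_net: PartialCorrelationNetwork
                     ) -> tuple[tuple[str, str], ...]:
    """Pairs present in both networks with opposite partial-correlation signs."""
    def signed(net):
        out = {}
        keep = net.network_nodes()
        for e in net.edges:
            if e.u in keep and e.v in keep:
                u, v = (e.u, e.v) if e.u <= e.v else (e.v, e.u)
                out[(u, v)] = 1 if e.pcor > 0 else -1
        return out

    meal, hab = signed(meal_net), signed(habitual_net)
    return tuple(sorted(p for p in meal.keys() & hab.keys()
                        if meal[p] != hab[p]))


def strength_comparison(networks: Mapping[str, PartialCorrelationNetwork]
                        ) -> dict[str, dict[str, float | None]]:
    """Mean and max |pcor| over each network's edges (None when empty)."""
    out: dict[str, dict[str, float | None]] = {}
    for name, net in networks.items():
        vals = [abs(e.pcor) for e in net.edges
                if e.u in net.network_nodes() and e.v in net.network_nodes()]
        if vals:
            out[name] = {"mean_abs_pcor": sum(vals) / len(vals),
                         "max_abs_pcor": max(vals), "n_edges": len(vals)}
        else:
            out[name] = {"mean_abs_pcor": None, "max_abs_pcor": None, "n_edges": 0}
    return out


@dataclass
class OverlapReport:
    """How meal networks are reflected in the habitual network."""

    per_meal: dict[str, dict]  # meal -> {n_edges, matched, percentage}
    habitual_unique_pct: float | None
    discordant_pairs: dict[str, tuple[tuple[str, str], ...]]
    strength: dict[str, dict[str, float | None]]
    sign_specific: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sign_specific": self.sign_specific,
            "per_meal": self.per_meal,
            "habitual_unique_pct": self.habitual_unique_pct,
            "discordant_pairs": {m: [list(p) for p in pairs]
                                 for m, pairs in self.discordant_pairs.items()},
            "strength": self.strength,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> None:
        lines = ["network\tn_edges\tmatched_in_habitual\tpercentage"]
        for meal, rec in self.per_meal.items():
            pct = "empty" if rec["percentage"] is None else f"{rec['percentage']:.1f}"
            lines.append(f"{meal}\t{rec['n_edges']}\t{rec['matched']}\t{pct}")
        hu = ("empty" if self.habitual_unique_pct is None
              else f"{self.habitual_unique_pct:.1f}")
        lines.append(f"habitual-only\t\t\t{hu}")
        Path(path).write_text("\n".join(lines) + "\n")


def compare_networks(meal_nets: Mapping[str, PartialCorrelationNetwork],
                     habitual_net: PartialCorrelationNetwork,
                     sign_specific: bool = True) -> OverlapReport:
    per_meal = {}
    discordant = {}
    for meal, net in meal_nets.items():
        matched, total, pct = edge_overlap(net, habitual_net, sign_specific)
        per_meal[meal] = {"n_edges": total, "matched": matched, "percentage": pct}
        discordant[meal] = sign_discordance(net, habitual_net)
    strength = strength_comparison({**meal_nets, "habitual": habitual_net})
    return OverlapReport(
        per_meal=per_meal,
        habitual_unique_pct=habitual_unique(habitual_net, list(meal_nets.values()),
                                            sign_specific),
        discordant_pairs=discordant,
        strength=strength,
        sign_specific=sign_specific,
    )
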