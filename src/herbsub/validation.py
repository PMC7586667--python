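"""External validation of the drug ranking and herb network filtering.

Selected (high replaceable score) and unselected drugs are compared on two
DrugBank-style free-text fields: oral LD50 in rat (mg/kg; smaller means
more toxic) and elimination half-life (hours).  Bucketed values such as
"2–4 h" take their median; "x +/- y" forms take the central value; day
units are converted to hours.  Profiles with no parseable number for a
metric are simply excluded from that metric's mean.

The herb–ingredient–target–disease (HITD) graph keeps only ingredients
passing the standard TCMSP admission filters — oral bioavailability
strictly above 30% and drug-likeness strictly above 0.18 — and only
diseases belonging to the focal drug's side-effect or indication set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

OB_THRESHOLD = 30.0
DL_THRESHOLD = 0.18

_NUM = r"\d+(?:\.\d+)?"
# en-dash, minus sign, hyphen, or the word "to" separate range endpoints
_RANGE_SEP = r"\s*(?:–|−|-|to)\s*"

_HOUR_UNITS = r"(?:h|hr|hrs|hour|hours)"
_DAY_UNITS = r"(?:d|day|days)"


class InsufficientDataError(ValueError):
    """A comparison group has no parseable values for a metric."""


@dataclass
class DrugProfile:
    drug: str
    ld50_text: str = ""
    half_life_text: str = ""

    @property
    def ld50_mg_per_kg(self) -> float | None:
        return parse_numeric_range(self.ld50_text, kind="toxicity")

    @property
    def half_life_hours(self) -> float | None:
        return parse_numeric_range(self.half_life_text, kind="half_life")


def _first_match(patterns: Sequence[tuple[re.Pattern[str], float]], text: str) -> float | None:
    """Return the value of the first pattern that matches, scaled by its factor.

    Range patterns yield the midpoint; plus/minus patterns yield the centre.
    """
    for pattern, factor in patterns:
        m = pattern.search(text)
        if m:
            groups = [g for g in m.groups() if g is not None]
            if len(groups) == 2:
                value = (float(groups[0]) + float(groups[1])) / 2.0
            else:
                value = float(groups[0])
            return value * factor
    return None


def parse_numeric_range(text: str, kind: str) -> float | None:
    """Extract a numeric toxicity (mg/kg) or half-life (hours) from free text.

    Returns None when the text carries no number with the expected unit
    (for example a narrative case report), which excludes the profile from
    group means downstream.
    """
    if kind not in ("toxicity", "half_life"):
        raise ValueError(f"unknown kind {kind!r}")
    if not text:
        return None
    text = text.replace("−", "-").replace("–", "-")

    if kind == "toxicity":
        patterns = [
            (re.compile(rf"({_NUM}){_RANGE_SEP}({_NUM})\s*mg/kg"), 1.0),
            (re.compile(rf"({_NUM})\s*\+/-\s*{_NUM}\s*mg/kg"), 1.0),
            (re.compile(rf"({_NUM})\s*mg/kg"), 1.0),
        ]
    else:
        patterns = [
            (re.compile(rf"({_NUM}){_RANGE_SEP}({_NUM})\s*{_HOUR_UNITS}\b"), 1.0),
            (re.compile(rf"({_NUM}){_RANGE_SEP}({_NUM})\s*{_DAY_UNITS}\b"), 24.0),
            (re.compile(rf"({_NUM})\s*\+/-\s*{_NUM}\s*{_HOUR_UNITS}\b"), 1.0),
            (re.compile(rf"({_NUM})\s*\+/-\s*{_NUM}\s*{_DAY_UNITS}\b"), 24.0),
            (re.compile(rf"({_NUM})\s*{_HOUR_UNITS}\b"), 1.0),
            (re.compile(rf"({_NUM})\s*{_DAY_UNITS}\b"), 24.0),
        ]
    return _first_match(patterns, text)


@dataclass
class GroupComparison:
    selected_toxicity: float
    unselected_toxicity: float
    selected_half_life: float
    unselected_half_life: float

    @property
    def toxicity_ratio(self) -> float:
        """Unselected over selected mean LD50: above 1 means the selected
        (obvious side-effect) drugs are on average more toxic."""
        return self.unselected_toxicity / self.selected_toxicity


def _metric_mean(profiles: Iterable[DrugProfile], attr: str, label: str) -> float:
    values = [v for p in profiles if (v := getattr(p, attr)) is not None]
    if not values:
        raise InsufficientDataError(f"no parseable {attr} values in {label} group")
    return fmean(values)


def group_comparison(
    selected: Sequence[DrugProfile], unselected: Sequence[DrugProfile]
) -> GroupComparison:
    """Mean toxicity and half-life per group, over parseable values only."""
    return GroupComparison(
        selected_toxicity=_metric_mean(selected, "ld50_mg_per_kg", "selected"),
        unselected_toxicity=_metric_mean(unselected, "ld50_mg_per_kg", "unselected"),
        selected_half_life=_metric_mean(selected, "half_life_hours", "selected"),
        unselected_half_life=_metric_mean(unselected, "half_life_hours", "unselected"),
    )


def read_profiles(path: str | Path) -> list[DrugProfile]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        DrugProfile(drug=row["drug"], ld50_text=row["ld50_text"], half_life_text=row["half_life_text"])
        for _, row in frame.iterrows()
    ]


def build_hitd_graph(
    herb_ingredients: pd.DataFrame,
    ingredient_targets: pd.DataFrame,
    target_diseases: pd.DataFrame,
    drug_diseases: set[str],
    ob_threshold: float = OB_THRESHOLD,
    dl_threshold: float = DL_THRESHOLD,
) -> nx.DiGraph:
    """Filtered herb→ingredient→target→disease graph for one focal drug.

    ``herb_ingredients`` needs columns (herb, ingredient, ob, dl);
    ``ingredient_targets`` (ingredient, target); ``target_diseases``
    (target, disease).  Ingredients at OB exactly 30 or DL exactly 0.18
    are excluded — the filters are strict.  Nodes left without any edge
    after filtering are dropped.
    """
    kept = herb_ingredients[
        (herb_ingredients["ob"] > ob_threshold) & (herb_ingredients["dl"] > dl_threshold)
    ]
    kept_ingredients = set(kept["ingredient"])

    graph = nx.DiGraph()
    for _, row in kept.iterrows():
        graph.add_node(row["herb"], node_type="herb")
        graph.add_node(row["ingredient"], node_type="ingredient", ob=row["ob"], dl=row["dl"])
        graph.add_edge(row["herb"], row["ingredient"])

    it = ingredient_targets[ingredient_targets["ingredient"].isin(kept_ingredients)]
    for _, row in it.iterrows():
        graph.add_node(row["target"], node_type="target")
        graph.add_edge(row["ingredient"], row["target"])

    retained_targets = {n for n, d in graph.nodes(data=True) if d["node_type"] == "target"}
    td = target_diseases[
        target_diseases["target"].isin(retained_targets)
        & target_diseases["disease"].isin(drug_diseases)
    ]
    for _, row in td.iterrows():
        graph.add_node(row["disease"], node_type="disease")
        graph.add_edge(row["target"], row["disease"])

    graph.remove_nodes_from([n for n in graph if graph.degree(n) == 0])
    return graph


def write_hitd_graph(graph: nx.DiGraph, path: str | Path) -> None:
    """Export the graph as a tab-separated edge list with node types."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tsource_type\ttarget\ttarget_type\n")
        for a, b in sorted(graph.edges()):
            fh.write(
                f"{a}\t{graph.nodes[a]['node_type']}\t{b}\t{graph.nodes[b]['node_type']}\n"
            )


def common_targets(
    drug_targets: set[str], herb_ingredient_targets: Mapping[str, set[str]]
) -> dict[str, list[str]]:
    """Map each drug target to the herb ingredients that also hit it.

    Targets reached by no ingredient are omitted.
    """
    out: dict[str, list[str]] = {}
    for target in sorted(drug_targets):
        hits = sorted(
            ing for ing, targets in herb_ingredient_targets.items() if target in targets
        )
        if hits:
            out[target] = hits
    return out
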