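"""Three-criterion classifier for 13C-labelled taxa in a DNA-SIP experiment.

A taxon is called labelled when, comparing its relative abundance (each pool
normalised to 100 %) across the four pools of a substrate's vial pair:

1. its abundance in the heavy pool of the 13C incubation exceeds 1.0 %;
2. its heavy-pool abundance in the 13C incubation exceeds its light-pool
   abundance there; and
3. its heavy-minus-light abundance difference in the 13C incubation exceeds
   the same difference in the matched 12C control incubation.

All three inequalities are strict. Duplicate vials are averaged per pool
before the criteria are applied (a per-replicate AND is available via
``replicate_rule``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceQuad",
    "LabelCall",
    "relative_abundance",
    "quads_from_pools",
    "classify_labelled",
    "classify_from_pools",
    "evaluate_recovery",
    "calls_to_frame",
]


@dataclass(frozen=True)
class AbundanceQuad:
    """The four pool abundances (%) entering the criteria for one taxon."""

    taxon: str
    heavy_13C: float
    light_13C: float
    heavy_12C: float
    light_12C: float

    def values(self):
        return (self.heavy_13C, self.light_13C, self.heavy_12C, self.light_12C)

    @property
    def complete(self) -> bool:
        return all(v is not None and np.isfinite(v) for v in self.values())


@dataclass(frozen=True)
class LabelCall:
    taxon: str
    c1: bool
    c2: bool
    c3: bool
    labelled: bool
    quad: AbundanceQuad
    uncallable: bool = False


def relative_abundance(counts: pd.Series) -> pd.Series:
    """Per-taxon relative abundance in %, summing to 100 within the pool."""
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("pool has zero total count; relative abundance undefined")
    return 100.0 * counts / total


def _mean_pool_abundance(pools, which: str) -> pd.Series:
    """Replicate-averaged relative abundance of one pool across usable vials."""
    shares = [relative_abundance(getattr(p, f"{which}_counts")) for p in pools if p.usable]
    if not shares:
        raise ValueError(f"no usable vial supplies a {which} pool")
    return pd.concat(shares, axis=1).fillna(0.0).mean(axis=1)


def quads_from_pools(pools_13C, pools_12C) -> list:
    """Assemble per-taxon abundance quads from 13C and matched 12C vial pools.

    Taxa absent from a pool get abundance 0 (absence is evidence, not
    missingness, in amplicon profiling).
    """
    h13 = _mean_pool_abundance(pools_13C, "heavy")
    l13 = _mean_pool_abundance(pools_13C, "light")
    h12 = _mean_pool_abundance(pools_12C, "heavy")
    l12 = _mean_pool_abundance(pools_12C, "light")
    taxa = sorted(set(h13.index) | set(l13.index) | set(h12.index) | set(l12.index))
    return [
        AbundanceQuad(
            taxon=t,
            heavy_13C=float(h13.get(t, 0.0)),
            light_13C=float(l13.get(t, 0.0)),
            heavy_12C=float(h12.get(t, 0.0)),
            light_12C=float(l12.get(t, 0.0)),
        )
        for t in taxa
    ]


def classify_labelled(quads, min_heavy_pct: float = 1.0) -> list:
    """Apply the three labelling criteria (all strict) to each taxon."""
    calls = []
    for q in quads:
        if not q.complete:
            calls.append(LabelCall(q.taxon, False, False, False, False, q, uncallable=True))
            continue
        c1 = q.heavy_13C > min_heavy_pct
        c2 = q.heavy_13C > q.light_13C
        c3 = (q.heavy_13C - q.light_13C) > (q.heavy_12C - q.light_12C)
        calls.append(LabelCall(q.taxon, c1, c2, c3, c1 and c2 and c3, q))
    return calls


def classify_from_pools(pools_13C, pools_12C, min_heavy_pct: float = 1.0, replicate_rule: str = "mean") -> list:
    """Classify directly from vial pools, handling duplicate vials.

    ``replicate_rule="mean"`` (default) averages pool abundances across
    replicates before applying the criteria; ``"all"`` applies the criteria
    to each replicate pair separately and labels a taxon only if every
    replicate pair labels it.
    """
    if replicate_rule == "mean":
        return classify_labelled(quads_from_pools(pools_13C, pools_12C), min_heavy_pct)
    if replicate_rule != "all":
        raise ValueError(f"unknown replicate_rule {replicate_rule!r}")
    if len(pools_13C) != len(pools_12C):
        raise ValueError("per-replicate AND needs paired 13C/12C vial lists of equal length")
    per_rep = [
        classify_labelled(quads_from_pools([p13], [p12]), min_heavy_pct)
        for p13, p12 in zip(pools_13C, pools_12C)
    ]
    merged = []
    for calls in zip(*per_rep):
        first = calls[0]
        merged.append(
            LabelCall(
                first.taxon,
                all(c.c1 for c in calls),
                all(c.c2 for c in calls),
                all(c.c3 for c in calls),
                all(c.labelled for c in calls),
                first.quad,
                uncallable=any(c.uncallable for c in calls),
            )
        )
    return merged


def evaluate_recovery(calls, truth) -> dict:
    """Confusion-matrix summary of calls against a ground-truth labelled set.

    ``truth`` maps taxon -> bool (or is a set of labelled taxa). Undefined
    ratios are reported as NaN alongside the raw counts.
    """
    if not isinstance(truth, dict):
        truth = {t: True for t in truth}
    call_taxa = {c.taxon for c in calls}
    if call_taxa.isdisjoint(truth) and truth:
        raise ValueError("call and truth taxon sets are disjoint")
    tp = fp = fn = tn = 0
    for c in calls:
        is_true = bool(truth.get(c.taxon, False))
        if c.labelled and is_true:
            tp += 1
        elif c.labelled:
            fp += 1
        elif is_true:
            fn += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    fdr = fp / (tp + fp) if tp + fp else float("nan")
    return {"sensitivity": sens, "specificity": spec, "fdr": fdr, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def calls_to_frame(calls) -> pd.DataFrame:
    """LabelCall records as a tidy table (one row per taxon)."""
    return pd.DataFrame(
        {
            "taxon": [c.taxon for c in calls],
            "heavy_13C": [c.quad.heavy_13C for c in calls],
            "light_13C": [c.quad.light_13C for c in calls],
            "heavy_12C": [c.quad.heavy_12C for c in calls],
            "light_12C": [c.quad.light_12C for c in calls],
            "c1": [c.c1 for c in calls],
            "c2": [c.c2 for c in calls],
            "c3": [c.c3 for c in calls],
            "labelled": [c.labelled for c in calls],
        }
    )
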