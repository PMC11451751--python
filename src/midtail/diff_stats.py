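"""Differential proteoform statistics and site-level comparison.

Differences between two treatment conditions are assessed per proteoform on
the pooled log2 normalized reporter intensities of its eligible scans: the
log2 fold change is the difference of condition means and significance
comes from a two-sided two-sample t-test at p < 0.05 (Welch by default).
Benjamini-Hochberg q-values are reported alongside but do not drive the
significance flag.

Site-level marginals (the abundance of, say, K9ac summed over every
proteoform carrying it) allow direct comparison with bottom-up
(site-centric) measurements via Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import RunDesign
from .mass_model import SHORT_MOD_CODES, Proteoform
from .quantify import ProteoformQuant

__all__ = [
    "DifferentialResult",
    "group_and_test",
    "marginalize_sites",
    "simulated_condition_sites",
    "compare_bottom_up",
    "volcano_table",
]


@dataclass(frozen=True)
class DifferentialResult:
    """Per-proteoform differential outcome between two conditions."""

    proteoform_id: str
    log2fc: float
    p_value: float
    q_value: float
    n_reference: int
    n_treatment: int
    mean_abundance: float
    significant: bool


def _pooled_condition_values(
    q: ProteoformQuant, design: RunDesign, condition: str
) -> list[float]:
    vals: list[float] = []
    for ch in design.condition_channels(condition):
        vals.extend(q.channel_log2.get(ch, []))
    return vals


def group_and_test(
    quants: Sequence[ProteoformQuant],
    design: RunDesign,
    treatment: str | None = None,
    reference: str | None = None,
    alpha: float = 0.05,
    welch: bool = True,
    min_obs: int = 2,
) -> tuple[list[DifferentialResult], list[str]]:
    """Two-sided t-test of pooled log2 reporter signals per proteoform.

    ``log2fc = mean(treatment) - mean(reference)``; the reference defaults to
    the condition of the first channel and the treatment to the other one.
    Proteoforms with fewer than ``min_obs`` observations in either condition
    are excluded from testing and returned as the second element
    (quantified-but-not-tested).  Significance is ``p < alpha`` on the raw
    p-value; BH q-values are attached for transparency only.
    """
    conditions = design.conditions
    if len(conditions) != 2:
        raise ValueError(f"differential testing needs exactly 2 conditions, got {conditions}")
    if reference is None:
        reference = conditions[0]
    if treatment is None:
        treatment = next(c for c in conditions if c != reference)

    tested: list[tuple[ProteoformQuant, list[float], list[float]]] = []
    untested: list[str] = []
    for q in quants:
        ref = _pooled_condition_values(q, design, reference)
        trt = _pooled_condition_values(q, design, treatment)
        if len(ref) < min_obs or len(trt) < min_obs:
            untested.append(q.proteoform_id)
            continue
        tested.append((q, ref, trt))

    results: list[DifferentialResult] = []
    pvals: list[float] = []
    for q, ref, trt in tested:
        t, p = sps.ttest_ind(trt, ref, equal_var=not welch)
        if math.isnan(p):  # zero variance in both groups with equal means
            p = 1.0
        pvals.append(float(p))
        results.append(
            DifferentialResult(
                proteoform_id=q.proteoform_id,
                log2fc=float(np.mean(trt) - np.mean(ref)),
                p_value=float(p),
                q_value=math.nan,
                n_reference=len(ref),
                n_treatment=len(trt),
                mean_abundance=q.abundance,
                significant=bool(p < alpha),
            )
        )
    if pvals:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        results = [
            DifferentialResult(
                r.proteoform_id, r.log2fc, r.p_value, float(qv),
                r.n_reference, r.n_treatment, r.mean_abundance, r.significant,
            )
            for r, qv in zip(results, qvals)
        ]
    results.sort(key=lambda r: (r.p_value, r.proteoform_id))
    return results, untested


# ---------------------------------------------------------------------------
# Site-level marginals and bottom-up comparison
# ---------------------------------------------------------------------------


def _site_label(p: Proteoform, pos: int, name: str) -> str:
    return f"{p.sequence[pos - 1]}{pos}{SHORT_MOD_CODES.get(name, name.lower())}"


def marginalize_sites(
    quants: Iterable[ProteoformQuant | tuple[Proteoform, float]],
    condition: str = "all",
) -> pd.DataFrame:
    """Collapse proteoform abundances to site-level modification abundances.

    The abundance of a site-mod label (e.g. ``K9ac``) is the summed
    abundance of every proteoform carrying that positioned modification —
    a linear marginal of the mixture.  Returns a DataFrame with columns
    ``site, condition, abundance`` sorted by site.
    """
    totals: dict[str, float] = {}
    for q in quants:
        if isinstance(q, ProteoformQuant):
            p, ab = q.proteoform, q.abundance
        else:
            p, ab = q
        if p is None:
            raise ValueError(f"proteoform object missing for {q!r}")
        for pos, name in p.mods:
            label = _site_label(p, pos, name)
            totals[label] = totals.get(label, 0.0) + ab
    rows = [
        {"site": site, "condition": condition, "abundance": ab}
        for site, ab in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["site", "condition", "abundance"])


def simulated_condition_sites(
    marginals: pd.DataFrame, conditions: Sequence[str]
) -> pd.DataFrame:
    """Replicate a single-condition marginal table across named conditions."""
    frames = []
    for cond in conditions:
        f = marginals.copy()
        f["condition"] = cond
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def compare_bottom_up(
    middle: pd.DataFrame, bottom: pd.DataFrame, min_shared: int = 3
) -> dict[str, dict]:
    """Pearson correlation of site-level abundances, per condition.

    Joins the two tables on site label within each condition present in both
    (a middle-down table with condition ``"all"`` matches every bottom-up
    condition).  Requires at least ``min_shared`` shared labels per
    condition.  Returns ``{condition: {"r": ..., "p": ..., "sites": [...]}}``.
    """
    out: dict[str, dict] = {}
    bottom_conditions = list(dict.fromkeys(bottom["condition"]))
    for cond in bottom_conditions:
        b = bottom[bottom["condition"] == cond]
        m = middle[middle["condition"].isin([cond, "all"])]
        merged = pd.merge(
            m[["site", "abundance"]],
            b[["site", "abundance"]],
            on="site",
            suffixes=("_middle", "_bottom"),
        ).sort_values("site")
        if len(merged) < min_shared:
            raise ValueError(
                f"condition {cond!r}: only {len(merged)} shared site labels (need {min_shared})"
            )
        r, p = sps.pearsonr(merged["abundance_middle"], merged["abundance_bottom"])
        out[cond] = {"r": float(r), "p": float(p), "sites": list(merged["site"])}
    return out


def volcano_table(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Plot-ready table: log2 fold change vs -log10 p with abundance.

    Ordered by ascending p-value (ties by id); the significance flag uses the
    strict ``p < 0.05`` threshold carried on each result.
    """
    rows = [
        {
            "proteoform": r.proteoform_id,
            "log2fc": r.log2fc,
            "neg_log10_p": -math.log10(r.p_value) if r.p_value > 0 else math.inf,
            "mean_abundance": r.mean_abundance,
            "significant": r.significant,
        }
        for r in sorted(results, key=lambda r: (r.p_value, r.proteoform_id))
    ]
    return pd.DataFrame(
        rows, columns=["proteoform", "log2fc", "neg_log10_p", "mean_abundance", "significant"]
    )
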