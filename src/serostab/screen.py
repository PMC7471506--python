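"""Module–trait screening and candidate filtering.

Module eigenproteins are correlated with clinical traits (Pearson, with the
usual Student-t p-value on n−2 degrees of freedom); modules passing a
liberal screening threshold (default p < 0.15, chosen for power at small
sample size — no multiple-testing correction at this filtering stage) are
retained, and their member proteins are reduced to a candidate set by
requiring both high module membership (|kME|) and high standardized
intramodular connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from serostab.network import GREY, ModulePartition

__all__ = [
    "module_trait_table",
    "retain_modules",
    "candidate_filter",
    "scan_cutoff",
    "CandidateSet",
]


@dataclass
class CandidateSet:
    """Candidate proteins for one trait after kME/connectivity filtering."""

    trait: str
    proteins: list[str]
    cutoff: float
    source_modules: dict[str, str]  # protein -> module


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from t = r·sqrt(n−2)/sqrt(1−r²), df n−2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait_table(
    mes: pd.DataFrame, traits: pd.DataFrame, p_screen: float = 0.15
) -> pd.DataFrame:
    """Correlate each module eigenprotein with each clinical trait.

    ``mes`` is subjects × modules; ``traits`` is a per-subject summary
    (either wide subjects × traits, or the long output of
    :func:`serostab.preprocess.summarize_repeats`). Returns one row per
    (module, trait) with Pearson r, the two-sided t-based p-value and a
    retained flag at the strict ``p < p_screen`` threshold. P-values are
    intentionally unadjusted: this step is a screening filter.
    """
    if {"subject_id", "outcome", "mean"}.issubset(traits.columns):
        traits = traits.pivot(index="subject_id", columns="outcome", values="mean")
    common = mes.index.intersection(traits.index)
    if len(common) < 4:
        raise ValueError("need at least 4 aligned subjects for screening")
    if len(common) < len(mes.index):
        warnings.warn(
            f"screening restricted to {len(common)} subjects present in both tables"
        )
    mes = mes.loc[common]
    traits = traits.loc[common]
    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        if np.std(y) == 0:
            warnings.warn(f"trait {trait!r} is constant; correlations undefined")
            for mod in mes.columns:
                rows.append((mod, trait, np.nan, np.nan, False))
            continue
        for mod in mes.columns:
            r, p = pearson_with_p(mes[mod].to_numpy(dtype=float), y)
            rows.append((mod, trait, r, p, bool(p < p_screen)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "retained"])


def retain_modules(table: pd.DataFrame, p_screen: float = 0.15) -> dict[str, list[str]]:
    """Modules retained per trait at the strict ``p < p_screen`` threshold."""
    out: dict[str, list[str]] = {}
    for trait, grp in table.groupby("trait", sort=True):
        keep = grp[grp["p"] < p_screen]["module"].tolist()
        out[trait] = sorted(keep)
    return out


def candidate_filter(
    partition: ModulePartition,
    retained: list[str],
    cutoff: float,
    trait: str = "",
) -> CandidateSet:
    """Filter retained-module members by |kME| and standardized connectivity.

    A protein is a candidate when it belongs to a retained (non-grey)
    module, its module membership to its own module satisfies |kME| ≥
    cutoff, and its standardized intramodular connectivity satisfies
    k̂ ≥ cutoff. Grey proteins are never candidates.
    """
    if partition.kme is None or partition.k_hat is None:
        raise ValueError("partition lacks kME/connectivity; run build_network first")
    proteins: list[str] = []
    source: dict[str, str] = {}
    for mid in retained:
        if mid == GREY or mid not in partition.kme.columns:
            continue
        for p in partition.members(mid):
            kme = partition.kme.loc[p, mid]
            khat = partition.k_hat.get(p, np.nan)
            if abs(kme) >= cutoff and khat >= cutoff:
                proteins.append(p)
                source[p] = mid
    return CandidateSet(
        trait=trait, proteins=proteins, cutoff=cutoff, source_modules=source
    )


def scan_cutoff(
    partition: ModulePartition,
    retained: list[str],
    grid: np.ndarray | None = None,
    band: tuple[int, int] = (10, 20),
    count_fn=None,
    trait: str = "",
) -> tuple[float, pd.DataFrame]:
    """Scan the kME/connectivity cutoff and pick the largest in-band value.

    For each cutoff in ``grid`` (default 0.50–0.75, step 0.01) the candidate
    set is formed; ``count_fn(candidates)`` (default: plain candidate count)
    maps it to the set size the band applies to — pass a callable that runs
    stability selection to apply the band to the post-selection set instead.
    Returns the largest cutoff whose count falls within ``band`` and the
    scan table; if no cutoff lands in the band, the cutoff minimizing the
    distance to the band is returned with a warning.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.7501, 0.01), 2)
    if count_fn is None:
        count_fn = lambda cand: len(cand.proteins)
    rows = []
    for c in grid:
        cand = candidate_filter(partition, retained, float(c), trait=trait)
        rows.append((float(c), len(cand.proteins), int(count_fn(cand))))
    table = pd.DataFrame(rows, columns=["cutoff", "n_candidates", "n_counted"])
    lo, hi = band
    in_band = table[(table["n_counted"] >= lo) & (table["n_counted"] <= hi)]
    if len(in_band):
        best = float(in_band["cutoff"].max())
    else:
        dist = np.where(
            table["n_counted"] < lo, lo - table["n_counted"], table["n_counted"] - hi
        )
        best = float(table.loc[int(np.argmin(dist)), "cutoff"])
        warnings.warn(
            f"no cutoff yields a set within {band}; "
            f"returning closest (cutoff={best})"
        )
    return best, table
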