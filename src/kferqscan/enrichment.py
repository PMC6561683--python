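"""Enrichment of motif-bearing protein groups in functional annotations.

The ranking statistic is the combined score -ln(p) * z, where p is a
one-sided Fisher exact enrichment probability and z compares the observed
annotated-in-group count against repeated random reassignments of the
annotation set over the background.  Also provides the compartment
chi-squared test of motif-group composition, compositional (ternary)
binning of per-protein motif content at 5% resolution, and the Jaccard
term-similarity export for enrichment-map tools.

No multiple-testing correction across terms is applied: terms are ranked
by the combined score, not by corrected p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from kferqscan.motif_engine import ProteinMotifSummary

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "read_annotations",
    "fisher_enrichment",
    "resampled_z",
    "combined_score",
    "enrich_terms",
    "top_terms",
    "compartment_chisq",
    "ternary_binning",
    "term_similarity",
]


@dataclass
class EnrichmentResult:
    term: str
    k: int  # annotated proteins in the group
    K: int  # group size
    n: int  # annotated proteins in the background
    N: int  # background size
    p: float
    z: float | None  # None when the resampling sd is zero
    combined: float | None


def read_annotations(path) -> dict[str, set]:
    """Read a term -> protein-set table from a two-column TSV
    (term_id, protein_id) or a GAF 2.x file (columns 2 and 5 used)."""
    terms: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 15:  # GAF 2.x record
                protein, term = parts[1], parts[4]
            elif len(parts) >= 2:
                term, protein = parts[0], parts[1]
            else:
                continue
            if term == "term_id":  # optional header
                continue
            terms.setdefault(term, set()).add(protein)
    return terms


def fisher_enrichment(group: set, term: set, background: set) -> tuple[int, int, int, int, float]:
    """One-sided Fisher exact test for over-representation of a term in a group.

    Returns ``(k, K, n, N, p)`` where k = annotated proteins in the group,
    K = group size, n = annotated proteins in the background, N =
    background size; p is the upper hypergeometric tail (probability of
    observing k or more annotated proteins in the group by chance).
    """
    if not group or not background:
        raise ValueError("group and background must be non-empty")
    if not group <= background:
        raise ValueError("group must be a subset of the background")
    term_bg = term & background
    k = len(group & term_bg)
    K = len(group)
    n = len(term_bg)
    N = len(background)
    _odds, p = stats.fisher_exact([[k, K - k], [n - k, N - K - n + k]], alternative="greater")
    return k, K, n, N, float(p)


def resampled_z(
    group: set,
    term: set,
    background: set,
    n_reps: int = 40,
    seed: int | np.random.Generator = 0,
) -> float | None:
    """Z-score of the observed in-group annotation count against random
    reassignments of the annotation set.

    Each replicate draws a uniformly random protein subset of the same
    size as the (background-restricted) annotation set and recounts the
    overlap with the group; z = (k_obs - mean) / sd over replicates.
    Returns None (flagged undefined) when the replicate counts have zero
    spread.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 resampling replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = sorted(background)
    term_size = len(term & background)
    group_mask = np.fromiter((p in group for p in bg), dtype=bool, count=len(bg))
    k_obs = len(group & term & background)
    k_rep = np.empty(n_reps, dtype=float)
    for r in range(n_reps):
        idx = rng.choice(len(bg), size=term_size, replace=False)
        k_rep[r] = group_mask[idx].sum()
    sd = k_rep.std(ddof=1)
    if sd == 0:
        return None
    return float((k_obs - k_rep.mean()) / sd)


def combined_score(p: float, z: float | None) -> float | None:
    """-ln(p) * z; None when z is undefined.  Zero when p == 1, negative
    when the group is depleted (z < 0)."""
    if z is None:
        return None
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return -math.log(p) * z


def enrich_terms(
    group: set,
    annotations: Mapping[str, set],
    background: set,
    n_reps: int = 40,
    seed: int | np.random.Generator = 0,
) -> list[EnrichmentResult]:
    """Fisher p, resampled z and combined score for every term."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = []
    for term_id in sorted(annotations):
        term = annotations[term_id]
        k, K, n, N, p = fisher_enrichment(group, term, background)
        z = resampled_z(group, term, background, n_reps=n_reps, seed=rng)
        if z is None:
            logger.info("term %s: zero resampling spread, z undefined", term_id)
        results.append(
            EnrichmentResult(term=term_id, k=k, K=K, n=n, N=N, p=p, z=z,
                             combined=combined_score(p, z))
        )
    return results


def top_terms(results: Sequence[EnrichmentResult], per_group: int = 5) -> list[EnrichmentResult]:
    """The most enriched terms ranked by combined score (descending), ties
    broken by smaller p then term id; terms with undefined z excluded."""
    defined = [r for r in results if r.combined is not None]
    ranked = sorted(defined, key=lambda r: (-r.combined, r.p, r.term))
    return ranked[:per_group]


def percent_annotated(result: EnrichmentResult) -> float:
    """Percent of the term's annotated proteins that fall in the group."""
    return 100.0 * result.k / result.n if result.n else 0.0


def compartment_chisq(
    compartment_counts: Mapping[str, int],
    proteome_counts: Mapping[str, int],
) -> tuple[float, float]:
    """Chi-squared goodness-of-fit of a compartment's hierarchy-group
    composition against whole-proteome proportions.

    Both mappings give counts per hierarchy group (canonical,
    phospho_generated, acetyl_generated, none).  Raises if any expected
    count is zero (merge categories first).
    """
    cats = sorted(set(compartment_counts) | set(proteome_counts))
    obs = np.array([compartment_counts.get(c, 0) for c in cats], dtype=float)
    ref = np.array([proteome_counts.get(c, 0) for c in cats], dtype=float)
    if ref.sum() == 0:
        raise ValueError("empty proteome reference")
    expected = ref / ref.sum() * obs.sum()
    if (expected == 0).any():
        bad = [c for c, e in zip(cats, expected) if e == 0]
        raise ValueError(f"zero expected count for {bad}; merge categories")
    stat, p = stats.chisquare(obs, expected)
    return float(stat), float(p)


def _ternary_bin(fractions: tuple, bin_size: float = 5.0) -> tuple:
    """Lower-edge coordinates of the simplex bin containing a (c, p, a)
    percent triple; the 100% edge folds into the top bin so every protein
    with motifs lands in exactly one bin."""
    n_bins = int(round(100.0 / bin_size))
    return tuple(min(int(f // bin_size), n_bins - 1) * bin_size for f in fractions)


def ternary_binning(
    summaries: Sequence[ProteinMotifSummary],
    term: set,
    background: set,
    bin_size: float = 5.0,
    n_reps: int = 40,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-bin term enrichment over the motif-composition simplex.

    Each motif-bearing protein is mapped to the 5%-resolution bin holding
    its (canonical%, phospho%, acetyl%) fractional content; each bin is
    then treated as a group and scored with Fisher p, resampled z and the
    combined score against the background.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins: dict[tuple, set] = {}
    for s in summaries:
        if s.fractional_content is None:
            continue
        bins.setdefault(_ternary_bin(s.fractional_content, bin_size), set()).add(s.protein_id)
    rows = []
    for coords in sorted(bins):
        members = bins[coords] & background
        if not members:
            continue
        k, K, n, N, p = fisher_enrichment(members, term, background)
        z = resampled_z(members, term, background, n_reps=n_reps, seed=rng)
        rows.append(
            {
                "canonical_bin": coords[0],
                "phospho_bin": coords[1],
                "acetyl_bin": coords[2],
                "n_proteins": K,
                "k": k,
                "p": p,
                "z": z,
                "combined": combined_score(p, z),
            }
        )
    return pd.DataFrame(rows)


def term_similarity(
    annotations: Mapping[str, set],
    min_jaccard: float = 0.0,
) -> pd.DataFrame:
    """Pairwise Jaccard similarity between annotation sets, for
    enrichment-map style network export; pairs below ``min_jaccard`` are
    omitted."""
    rows = []
    for a, b in combinations(sorted(annotations), 2):
        sa, sb = annotations[a], annotations[b]
        union = len(sa | sb)
        j = len(sa & sb) / union if union else 0.0
        if j >= min_jaccard:
            rows.append({"term_a": a, "term_b": b, "jaccard": j})
    return pd.DataFrame(rows, columns=["term_a", "term_b", "jaccard"])
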