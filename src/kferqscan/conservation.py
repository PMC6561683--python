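"""Cross-species conservation of KFERQ-like motifs.

Classifies species proteomes as CMA-able or CMA-unable via the LAMP-2A
C-terminal tail signature, extracts the alignment columns of a human motif
from an ortholog multiple sequence alignment, classifies each species'
residues at those columns, and scores conservation per species group as

    score = (n_conserved + 0.5 * n_partial - n_noOrtholog) / n_species

so that fully conserved families score 1 and families with no detectable
orthologs score -1.  A species whose ortholog lacks any motif at the human
position (``absent_motif``) contributes zero to the numerator but still
counts in the denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from kferqscan.motif_engine import MotifClass, MotifMatch, classify_window

__all__ = [
    "LAMP2A_TAIL_PATTERN",
    "SpeciesClassification",
    "OrthologFamily",
    "ConservationRecord",
    "lamp2a_tail_classify",
    "map_motif_to_alignment",
    "classify_species_motif",
    "conservation_score",
    "score_family",
    "group_comparison",
]

#: C-terminal signature of the CMA receptor LAMP-2A: 3-4 consecutive basic
#: residues, a 1-3 residue spacer, then GYEQF at the absolute C-terminus.
LAMP2A_TAIL_PATTERN = re.compile(r"[KRH]{3,4}.{1,3}GYEQF$")

GAP_CHARS = frozenset("-.")


class SpeciesClassification(str, Enum):
    CONSERVED = "conserved"
    PARTIAL = "partial"
    ABSENT_MOTIF = "absent_motif"
    NO_ORTHOLOG = "no_ortholog"


@dataclass
class OrthologFamily:
    """One human protein, its single canonical motif, and the aligned
    ortholog sequences keyed by species name (gapped, equal length)."""

    human_id: str
    human_motif: MotifMatch
    aligned: Mapping[str, str]  # species -> gapped sequence; must include human_id
    human_species: str = "human"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) > 1:
            raise ValueError(f"family {self.human_id}: unequal alignment row lengths")
        if self.human_species not in self.aligned:
            raise ValueError(f"family {self.human_id}: no row for {self.human_species!r}")

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.aligned.values())))


@dataclass
class ConservationRecord:
    """Per-group tallies and score for one human motif."""

    human_id: str
    n_conserved: int
    n_partial: int
    n_absent: int
    n_no_ortholog: int

    @property
    def n_species(self) -> int:
        return self.n_conserved + self.n_partial + self.n_absent + self.n_no_ortholog

    @property
    def score(self) -> float:
        return conservation_score(
            self.n_conserved, self.n_partial, self.n_no_ortholog, self.n_species
        )


def lamp2a_tail_classify(sequence: str, tail_window: int = 100) -> bool:
    """True iff the C-terminus carries the LAMP-2A tail signature.

    Only the last ``tail_window`` residues are examined; the pattern
    requires 3-4 consecutive K/R/H, 1-3 arbitrary residues, and a terminal
    GYEQF.  Sequences shorter than the minimal tail (9 residues) are
    rejected.
    """
    if len(sequence) < 9:
        return False
    return LAMP2A_TAIL_PATTERN.search(sequence[-tail_window:]) is not None


def map_motif_to_alignment(family: OrthologFamily) -> list[int]:
    """Alignment columns (0-based) of the human motif's five residues.

    Gap columns in the human row are skipped, so the returned columns may
    be non-contiguous.  Raises if the human row cannot supply five
    residues at the motif coordinates or the reconstructed pentapeptide
    disagrees with the recorded motif.
    """
    human_row = family.aligned[family.human_species]
    motif = family.human_motif
    cols: list[int] = []
    residue_idx = 0  # 1-based position on the ungapped human sequence
    for col, ch in enumerate(human_row):
        if ch in GAP_CHARS:
            continue
        residue_idx += 1
        if motif.start <= residue_idx <= motif.end:
            cols.append(col)
        if residue_idx == motif.end:
            break
    if len(cols) != 5:
        raise ValueError(
            f"family {family.human_id}: motif at {motif.start}-{motif.end} "
            f"not reconstructable from the alignment"
        )
    penta = "".join(human_row[c] for c in cols)
    if penta != motif.pentapeptide:
        raise ValueError(
            f"family {family.human_id}: alignment residues {penta!r} do not "
            f"match the recorded motif {motif.pentapeptide!r}"
        )
    return cols


def _window_classes(pentapeptide: str, include_n: bool = False) -> set[MotifClass]:
    classes = {cls for cls, _orient in classify_window(pentapeptide, advanced_n=include_n)}
    if not include_n:
        classes = {c for c in classes if not c.is_n_class}
    return classes


def classify_species_motif(
    family: OrthologFamily,
    species: str,
    columns: Sequence[int],
    include_n: bool = False,
) -> SpeciesClassification:
    """Classify motif conservation for one species at the human motif columns.

    ``conserved``: the species' pentapeptide at those columns yields a
    motif of the same class as the human motif (either orientation);
    ``partial``: it yields only motifs of a different class;
    ``absent_motif``: no motif, or a gap inside the extracted window;
    ``no_ortholog``: the species has no row in the alignment.
    """
    row = family.aligned.get(species)
    if row is None:
        return SpeciesClassification.NO_ORTHOLOG
    penta = "".join(row[c] for c in columns).upper()
    if any(ch in GAP_CHARS for ch in penta):
        return SpeciesClassification.ABSENT_MOTIF
    classes = {c.main_class for c in _window_classes(penta, include_n)}
    if not classes:
        return SpeciesClassification.ABSENT_MOTIF
    human_class = family.human_motif.motif_class.main_class
    if human_class in classes:
        return SpeciesClassification.CONSERVED
    return SpeciesClassification.PARTIAL


def conservation_score(
    n_conserved: int, n_partial: int, n_no_ortholog: int, n_species: int
) -> float:
    """(n_conserved + 0.5*n_partial - n_noOrtholog) / n_species, in [-1, 1]."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if n_conserved + n_partial + n_no_ortholog > n_species:
        raise ValueError("tallies exceed n_species")
    return (n_conserved + 0.5 * n_partial - n_no_ortholog) / n_species


def score_family(
    family: OrthologFamily,
    species: Sequence[str],
    include_n: bool = False,
) -> ConservationRecord:
    """Tally species classifications for one family over a species set.

    Species listed but missing from the alignment count as no-ortholog;
    the human reference row itself is not tallied unless listed.
    """
    cols = map_motif_to_alignment(family)
    tally = {c: 0 for c in SpeciesClassification}
    for sp in species:
        tally[classify_species_motif(family, sp, cols, include_n)] += 1
    return ConservationRecord(
        human_id=family.human_id,
        n_conserved=tally[SpeciesClassification.CONSERVED],
        n_partial=tally[SpeciesClassification.PARTIAL],
        n_absent=tally[SpeciesClassification.ABSENT_MOTIF],
        n_no_ortholog=tally[SpeciesClassification.NO_ORTHOLOG],
    )


def group_comparison(
    families: Sequence[OrthologFamily],
    species_table: Mapping[str, bool],
    include_n: bool = False,
) -> pd.DataFrame:
    """Score each family separately over CMA-able and CMA-unable species.

    ``species_table`` maps species name -> CMA-able flag.  Returns one row
    per family with both scores, the tallies, and the selective-
    conservation flag (score_able > 0 and score_unable <= 0, i.e. the
    motif is more likely than not conserved in CMA-able species and not in
    CMA-unable ones).
    """
    able = [sp for sp, ok in species_table.items() if ok]
    unable = [sp for sp, ok in species_table.items() if not ok]
    if not able or not unable:
        raise ValueError("both species groups must be non-empty")
    rows = []
    for fam in families:
        rec_a = score_family(fam, able, include_n)
        rec_u = score_family(fam, unable, include_n)
        rows.append(
            {
                "protein": fam.human_id,
                "score_able": rec_a.score,
                "score_unable": rec_u.score,
                "able_conserved": rec_a.n_conserved,
                "able_partial": rec_a.n_partial,
                "able_absent": rec_a.n_absent,
                "able_no_ortholog": rec_a.n_no_ortholog,
                "unable_conserved": rec_u.n_conserved,
                "unable_partial": rec_u.n_partial,
                "unable_absent": rec_u.n_absent,
                "unable_no_ortholog": rec_u.n_no_ortholog,
                "selective": rec_a.score > 0 and rec_u.score <= 0,
            }
        )
    return pd.DataFrame(rows)
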