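"""The KFERQ-like motif grammar: window classification and protein scanning.

A KFERQ-like motif is a pentapeptide composed of a *flank* residue at the
first or last position and four *variable* residues.  The variable region
must contain one or two basic residues (K/R), one or two hydrophobic
residues (I/L/V/F) and exactly one "acidic slot" residue, with the three
categories filling all four positions.  The identity of the flank and of
the acidic slot defines the motif class:

==========================  =====  ===========================
class                       flank  acidic slot
==========================  =====  ===========================
canonical                   Q      D or E
phosphorylation-generated   Q      S, T or Y (acidic once
                                   phosphorylated); no D/E
                                   allowed in the region
acetylation-generated       K      D or E (the flank lysine is
                                   acidic once acetylated)
==========================  =====  ===========================

In *advanced* mode an asparagine may substitute for the flanking glutamine,
yielding the ``n_canonical``/``n_phospho`` classes.  These N-bearing motifs
are necessary but not sufficient for HSC70 recognition and are therefore
kept out of the default scan.  The ``n_acetyl`` label exists in the class
enumeration for completeness but is unreachable from the grammar: the
acetylation-generated class has a lysine flank, so the N-for-Q substitution
cannot apply to it.

Coordinates are 1-based and inclusive in every public structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "MotifClass",
    "MotifMatch",
    "MotifRules",
    "Orientation",
    "ProteinMotifSummary",
    "classify_window",
    "classify_variable_region",
    "flag_ubiquitylation_sensitive",
    "scan_protein",
    "summarize_protein",
]

#: The 20 standard amino acids (one-letter codes).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MotifClass(str, Enum):
    """Motif classes, ordered by the grouping hierarchy (canonical first)."""

    CANONICAL = "canonical"
    PHOSPHO = "phospho_generated"
    ACETYL = "acetyl_generated"
    N_CANONICAL = "n_canonical"
    N_PHOSPHO = "n_phospho"
    N_ACETYL = "n_acetyl"  # unreachable from the grammar; see module docstring

    @property
    def is_n_class(self) -> bool:
        return self.value.startswith("n_")

    @property
    def main_class(self) -> "MotifClass":
        """Map N-bearing classes onto their Q-flanked counterpart."""
        return _N_TO_MAIN.get(self, self)


_N_TO_MAIN = {
    MotifClass.N_CANONICAL: MotifClass.CANONICAL,
    MotifClass.N_PHOSPHO: MotifClass.PHOSPHO,
    MotifClass.N_ACETYL: MotifClass.ACETYL,
}

#: Hierarchy used for protein grouping: canonical > phospho > acetyl.
HIERARCHY = (MotifClass.CANONICAL, MotifClass.PHOSPHO, MotifClass.ACETYL)


class Orientation(str, Enum):
    """Position of the flank residue: last (Q_right) or first (Q_left)."""

    Q_RIGHT = "Q_right"
    Q_LEFT = "Q_left"


@dataclass(frozen=True)
class MotifRules:
    """Residue categories and count constraints of the motif grammar."""

    basic_set: frozenset = frozenset("KR")
    hydrophobic_set: frozenset = frozenset("ILVF")
    acidic_set: frozenset = frozenset("DE")
    phospho_set: frozenset = frozenset("STY")
    flank_canonical: str = "Q"
    flank_acetyl: str = "K"
    flank_advanced: str = "N"
    basic_count_range: tuple = (1, 2)
    hydrophobic_count_range: tuple = (1, 2)
    acidic_count: int = 1

    def __post_init__(self) -> None:
        sets = [self.basic_set, self.hydrophobic_set, self.acidic_set, self.phospho_set]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a & b:
                    raise ValueError("motif residue categories must be disjoint")


DEFAULT_RULES = MotifRules()


@dataclass(frozen=True)
class MotifMatch:
    """One oriented pentapeptide hit on a protein.

    ``start``/``end`` are 1-based inclusive residue indices with
    ``end == start + 4``; ``center`` marks the third residue and is the
    coordinate used for positional analyses.
    """

    protein_id: str
    start: int
    pentapeptide: str
    orientation: Orientation
    motif_class: MotifClass
    ubiquitylation_sensitive: bool = False

    @property
    def end(self) -> int:
        return self.start + 4

    @property
    def center(self) -> int:
        return self.start + 2

    @property
    def variable_region(self) -> str:
        """The four variable residues, read from the flank outward is NOT
        implied; this is simply the window minus the flank residue."""
        if self.orientation is Orientation.Q_RIGHT:
            return self.pentapeptide[:4]
        return self.pentapeptide[1:]


@dataclass
class ProteinMotifSummary:
    """Per-protein motif tally, hierarchy group and fractional composition."""

    protein_id: str
    length: int
    counts: Mapping[MotifClass, int]
    hierarchy_group: str
    combination_signature: frozenset
    fractional_content: tuple | None  # (canonical%, phospho%, acetyl%), None if no motif


def classify_variable_region(region: str, rules: MotifRules = DEFAULT_RULES) -> MotifClass | None:
    """Classify a 4-residue variable region under the unmodified (canonical /
    acetyl) or phosphorylation-generated composition rule.

    Returns :data:`MotifClass.CANONICAL` for the unmodified rule (the caller
    maps it to acetyl or the N classes depending on the flank),
    :data:`MotifClass.PHOSPHO` for the phospho rule, or ``None``.
    """
    b = h = a = p = 0
    for aa in region:
        if aa in rules.basic_set:
            b += 1
        elif aa in rules.hydrophobic_set:
            h += 1
        elif aa in rules.acidic_set:
            a += 1
        elif aa in rules.phospho_set:
            p += 1
        else:
            return None
    lo_b, hi_b = rules.basic_count_range
    lo_h, hi_h = rules.hydrophobic_count_range
    if not (lo_b <= b <= hi_b and lo_h <= h <= hi_h):
        return None
    if a == rules.acidic_count and p == 0:
        return MotifClass.CANONICAL
    if p == rules.acidic_count and a == 0:
        return MotifClass.PHOSPHO
    return None


def classify_window(
    pentapeptide: str,
    advanced_n: bool = False,
    rules: MotifRules = DEFAULT_RULES,
) -> list[tuple[MotifClass, Orientation]]:
    """Return every (class, orientation) pair a 5-residue window satisfies.

    The flank residue is read at the last position (``Q_right``) and at the
    first position (``Q_left``); for each orientation the remaining four
    residues are tested against the composition rules.  A window can match
    in both orientations (e.g. ``KKFEK``, where lysine serves as flank on
    either end), and each oriented reading yields at most one class.

    Non-standard letters (X, B, Z, J, U, O, gaps) never satisfy any
    category, so windows containing them silently fail to match; wrong
    length or lowercase input raises :class:`ValueError`.
    """
    if len(pentapeptide) != 5:
        raise ValueError(f"expected a 5-residue window, got {len(pentapeptide)} residues")
    if pentapeptide != pentapeptide.upper():
        raise ValueError("window must be uppercase one-letter amino-acid codes")

    hits: list[tuple[MotifClass, Orientation]] = []
    for orientation in (Orientation.Q_LEFT, Orientation.Q_RIGHT):
        if orientation is Orientation.Q_RIGHT:
            flank, region = pentapeptide[4], pentapeptide[:4]
        else:
            flank, region = pentapeptide[0], pentapeptide[1:]
        base = classify_variable_region(region, rules)
        if base is None:
            continue
        if flank == rules.flank_canonical:
            hits.append((base, orientation))
        elif flank == rules.flank_acetyl and base is MotifClass.CANONICAL:
            # The acetyl-lysine flank supplies the acidity the Q supplies in
            # the canonical class; a second simultaneous PTM (phospho slot)
            # is not allowed, so only the unmodified region rule qualifies.
            hits.append((MotifClass.ACETYL, orientation))
        elif advanced_n and flank == rules.flank_advanced:
            n_class = MotifClass.N_CANONICAL if base is MotifClass.CANONICAL else MotifClass.N_PHOSPHO
            hits.append((n_class, orientation))
    return hits


def flag_ubiquitylation_sensitive(pentapeptide: str) -> bool:
    """True iff the window contains a lysine whose ubiquitylation would
    inactivate the motif.  Pure annotation; never affects classification."""
    return "K" in pentapeptide


def scan_protein(
    sequence: str,
    protein_id: str = "",
    advanced_n: bool = False,
    flag_ubiquitylation: bool = False,
    rules: MotifRules = DEFAULT_RULES,
) -> list[MotifMatch]:
    """Scan every 5-residue window of a protein for KFERQ-like motifs.

    Overlapping windows are all tested and one :class:`MotifMatch` is
    emitted per (window, class, orientation) hit, sorted by start position.
    Sequences shorter than 5 residues yield an empty list; windows
    containing non-standard letters never match but do not abort the scan.
    """
    matches: list[MotifMatch] = []
    n = len(sequence)
    if n < 5:
        return matches
    if sequence != sequence.upper():
        raise ValueError(f"protein {protein_id or '<unnamed>'}: sequence must be uppercase")
    for i in range(n - 4):
        window = sequence[i : i + 5]
        for motif_class, orientation in classify_window(window, advanced_n=advanced_n, rules=rules):
            matches.append(
                MotifMatch(
                    protein_id=protein_id,
                    start=i + 1,
                    pentapeptide=window,
                    orientation=orientation,
                    motif_class=motif_class,
                    ubiquitylation_sensitive=(
                        flag_ubiquitylation_sensitive(window) if flag_ubiquitylation else False
                    ),
                )
            )
    return matches


def summarize_protein(
    matches: Sequence[MotifMatch],
    protein_id: str,
    length: int,
) -> ProteinMotifSummary:
    """Summarize one protein's matches into counts, hierarchy group,
    combination signature and fractional motif content.

    The hierarchy group is the highest-ranking class present (canonical >
    phosphorylation-generated > acetylation-generated, else ``"none"``).
    N-bearing classes are tallied in ``counts`` but excluded from the
    signature and from the fractional content, which is computed over the
    three main classes and sums to 100% whenever any main-class motif
    exists (a protein with two canonical, one phospho- and one
    acetyl-generated motif has fractional content (50, 25, 25)).
    """
    counts: dict[MotifClass, int] = {c: 0 for c in MotifClass}
    for m in matches:
        if m.protein_id and protein_id and m.protein_id != protein_id:
            raise ValueError("matches from multiple proteins passed to summarize_protein")
        counts[m.motif_class] += 1

    group = "none"
    for cls in HIERARCHY:
        if counts[cls] > 0:
            group = cls.value
            break

    signature = frozenset(c.value for c in HIERARCHY if counts[c] > 0)
    total = sum(counts[c] for c in HIERARCHY)
    fractional = None
    if total > 0:
        fractional = tuple(100.0 * counts[c] / total for c in HIERARCHY)

    return ProteinMotifSummary(
        protein_id=protein_id,
        length=length,
        counts=counts,
        hierarchy_group=group,
        combination_signature=signature,
        fractional_content=fractional,
    )


def summarize_proteome(
    records: Iterable,
    advanced_n: bool = False,
    rules: MotifRules = DEFAULT_RULES,
) -> tuple[list[ProteinMotifSummary], list[MotifMatch]]:
    """Scan and summarize every record of a proteome.

    ``records`` may be :class:`~kferqscan.io.ProteinRecord` objects or any
    object with ``accession``/``sequence`` attributes.  Returns the
    per-protein summaries and the flat list of all matches.
    """
    summaries: list[ProteinMotifSummary] = []
    all_matches: list[MotifMatch] = []
    for rec in records:
        pid = getattr(rec, "accession", None) or getattr(rec, "protein_id", "")
        seq = rec.sequence
        matches = scan_protein(seq, protein_id=pid, advanced_n=advanced_n, rules=rules)
        summaries.append(summarize_protein(matches, pid, len(seq)))
        all_matches.extend(matches)
    return summaries, all_matches
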