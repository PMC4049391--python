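"""In-silico restriction digestion and CAPS-style variant discrimination.

Near-identical paralogous amplicons that cannot be told apart by plain
electrophoresis can often be discriminated after digestion with an enzyme
whose recognition site is polymorphic among the variants (a cleaved
amplified polymorphic sequence, CAPS, assay).  This module predicts cut
sites and fragment patterns for linear double-stranded amplicons, groups
fragments into co-migrating gel band classes, flags the bands that are
diagnostic for a single variant, and ranks candidate enzymes by how many
variants they discriminate.

Conventions
-----------
Coordinates are 1-based.  A cut at coordinate ``c`` splits ``[1..c]`` from
``[c+1..L]``, so ``c`` equals the length of the prefix fragment.  For a
recognition motif starting at 1-based position ``p`` with top-strand cut
offset ``o`` (bases from the motif's 5' end), the cut coordinate is
``c = p + o - 1``.  Digestion is of linear molecules and assumed complete;
cuts falling exactly at either molecule end are discarded (they would
produce zero-length fragments).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .errors import ConfigError, ValidationError

#: IUPAC nucleotide codes and the concrete bases each matches.  Ambiguity
#: codes are legal in motifs (set-match semantics) but a non-ACGT character
#: in the *sequence* never matches any motif position.
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif and top-strand cut offset.

    ``cut_offset`` counts bases from the 5' end of the motif on the top
    strand; ClaI (AT^CGAT) has motif ``ATCGAT`` and offset 2.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        object.__setattr__(self, "recognition", motif)
        if len(motif) < 4:
            raise ConfigError(
                f"enzyme {self.name!r}: recognition motif {motif!r} shorter than 4 bp"
            )
        bad = sorted(set(motif) - set(IUPAC_DNA))
        if bad:
            raise ConfigError(
                f"enzyme {self.name!r}: invalid IUPAC character(s) {bad} in motif {motif!r}"
            )
        if not 0 <= self.cut_offset <= len(motif):
            raise ConfigError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside [0, {len(motif)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


@dataclass(frozen=True)
class SequenceVariant:
    """One DNA variant (an amplicon / ORF) identified by ``id``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = sorted(set(seq) - set(IUPAC_DNA))
        if bad:
            raise ValidationError(
                f"variant {self.id!r}: non-IUPAC character(s) {bad} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestPattern:
    """Cut coordinates and resulting fragment multiset for one variant."""

    variant_id: str
    length: int
    cut_coords: tuple[int, ...]
    fragments: tuple[int, ...]  # sorted descending, gel order

    def fragment_multiset(self) -> Counter:
        return Counter(self.fragments)


@dataclass
class BandClass:
    """Co-migrating fragments: one band on the gel."""

    representative_length: float
    members: list[tuple[str, int]]  # (variant_id, fragment length)
    diagnostic: bool
    variants: frozenset[str]
    #: fragments under ~50 bp routinely run off or stain too weakly
    likely_detectable: bool = True


@dataclass
class BandTable:
    """Partition of all digest fragments into gel band classes."""

    classes: list[BandClass]
    tolerance: float

    def diagnostic_for(self, variant_id: str) -> list[BandClass]:
        return [c for c in self.classes if c.diagnostic and variant_id in c.variants]

    def shared(self) -> list[BandClass]:
        return [c for c in self.classes if not c.diagnostic]


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        b if len(IUPAC_DNA[b]) == 1 else "[" + IUPAC_DNA[b] + "]" for b in motif
    )
    return re.compile(r"(?=" + body + r")")


def _scan(sequence: str, motif: str) -> list[int]:
    """1-based start positions of motif occurrences on the given strand."""
    return [m.start() + 1 for m in _motif_regex(motif).finditer(sequence)]


def find_cut_sites(variant: SequenceVariant, enzyme: EnzymeSpec) -> DigestPattern:
    """Locate every double-strand cut ``enzyme`` makes in ``variant``.

    Palindromic motifs are scanned on the top strand only (the bottom-strand
    occurrence coincides); non-palindromic motifs are additionally searched
    as their reverse complement, with the top-strand cut coordinate of a
    bottom-strand site at ``p + (m - o) - 1``.  Cuts at coordinate 0 or L
    are discarded.  Returns a pattern whose fragments are also filled in
    (see :func:`digest`).
    """
    seq = variant.sequence
    m = len(enzyme.recognition)
    coords: set[int] = set()
    for p in _scan(seq, enzyme.recognition):
        coords.add(p + enzyme.cut_offset - 1)
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.recognition)
        for p in _scan(seq, rc):
            coords.add(p + (m - enzyme.cut_offset) - 1)
    L = variant.length
    cut_coords = tuple(sorted(c for c in coords if 0 < c < L))
    edges = (0,) + cut_coords + (L,)
    fragments = tuple(
        sorted((edges[i + 1] - edges[i] for i in range(len(edges) - 1)), reverse=True)
    )
    return DigestPattern(variant.id, L, cut_coords, fragments)


def digest(variant: SequenceVariant, enzyme: EnzymeSpec) -> DigestPattern:
    """Complete digestion of a linear molecule: cut sites plus fragments.

    Fragments are the successive differences of ``[0, cuts..., L]``; their
    sum always equals the sequence length.
    """
    if variant.length == 0:
        raise ValidationError(f"variant {variant.id!r}: empty sequence")
    return find_cut_sites(variant, enzyme)


def _relative_difference(a: float, b: float) -> float:
    if a == b:
        return 0.0
    return abs(a - b) / ((a + b) / 2.0)


def classify_bands(
    patterns: Sequence[DigestPattern],
    tolerance: float = 0.02,
    min_detectable_bp: int = 50,
) -> BandTable:
    """Group fragments from several digests into co-migrating band classes.

    Single-linkage clustering on relative length difference (|Δ|/mean);
    in one dimension this reduces to chaining sorted lengths whose adjacent
    gap is within ``tolerance``.  A class is *diagnostic* iff all its member
    fragments come from a single variant, which makes that band a
    fingerprint for the variant on a gel.
    """
    if not patterns:
        raise ValidationError("classify_bands: empty pattern list")
    if not 0 <= tolerance <= 0.2:
        raise ValidationError(f"tolerance {tolerance} outside [0, 0.2]")
    frags: list[tuple[int, str]] = []
    for pat in patterns:
        frags.extend((f, pat.variant_id) for f in pat.fragments)
    frags.sort()
    classes: list[BandClass] = []
    cluster: list[tuple[int, str]] = []
    for item in frags:
        if cluster and _relative_difference(cluster[-1][0], item[0]) > tolerance:
            classes.append(_make_class(cluster, min_detectable_bp))
            cluster = []
        cluster.append(item)
    if cluster:
        classes.append(_make_class(cluster, min_detectable_bp))
    classes.sort(key=lambda c: -c.representative_length)
    return BandTable(classes=classes, tolerance=tolerance)


def _make_class(cluster: list[tuple[int, str]], min_detectable_bp: int) -> BandClass:
    lengths = [length for length, _ in cluster]
    variants = frozenset(vid for _, vid in cluster)
    rep = sum(lengths) / len(lengths)
    return BandClass(
        representative_length=rep,
        members=[(vid, length) for length, vid in cluster],
        diagnostic=len(variants) == 1,
        variants=variants,
        likely_detectable=rep >= min_detectable_bp,
    )


@dataclass
class ScreenResult:
    enzyme: EnzymeSpec
    score: int  # variants with at least one diagnostic band
    n_bands: int
    full_discrimination: bool
    bands: BandTable = field(repr=False, default=None)


def screen_enzymes(
    variants: Sequence[SequenceVariant],
    enzymes: Sequence[EnzymeSpec],
    tolerance: float = 0.02,
) -> list[ScreenResult]:
    """Rank candidate enzymes by how many variants they fingerprint.

    The score of an enzyme is the number of variants that possess at least
    one diagnostic band after digestion with it; ties are broken in favour
    of the enzyme producing fewer bands (a simpler gel).  Distinct uncut
    lengths count: if an enzyme cuts nothing but the variants differ in
    length beyond the co-migration tolerance, the full-length bands are
    themselves diagnostic.
    """
    if len(variants) < 2:
        raise ValidationError("screen_enzymes: need at least 2 variants")
    if not enzymes:
        raise ValidationError("screen_enzymes: empty enzyme table")
    results = []
    for enz in enzymes:
        patterns = [digest(v, enz) for v in variants]
        bands = classify_bands(patterns, tolerance)
        score = sum(1 for v in variants if bands.diagnostic_for(v.id))
        results.append(
            ScreenResult(
                enzyme=enz,
                score=score,
                n_bands=len(bands.classes),
                full_discrimination=score == len(variants),
                bands=bands,
            )
        )
    results.sort(key=lambda r: (-r.score, r.n_bands, r.enzyme.name))
    return results


def load_enzyme_table(path=None) -> list[EnzymeSpec]:
    """Read a TSV enzyme table (columns: name, recognition, cut_offset).

    With no path, the built-in table of common 6-cutters is returned.
    """
    if path is None:
        text = (resources.files("capskit") / "data" / "enzymes.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    required = ["name", "recognition", "cut_offset"]
    if header[:3] != required:
        raise ConfigError(
            f"enzyme table must have columns {required}, found {header[:3]}"
        )
    enzymes = []
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ConfigError(f"malformed enzyme table row: {ln!r}")
        try:
            offset = int(fields[2])
        except ValueError as exc:
            raise ConfigError(f"non-integer cut_offset in row {ln!r}") from exc
        enzymes.append(EnzymeSpec(fields[0], fields[1], offset))
    if not enzymes:
        raise ConfigError("enzyme table contains no enzymes")
    return enzymes


def get_enzyme(name: str, table: Iterable[EnzymeSpec] | None = None) -> EnzymeSpec:
    table = list(table) if table is not None else load_enzyme_table()
    for enz in table:
        if enz.name.lower() == name.lower():
            return enz
    raise ConfigError(f"enzyme {name!r} not found in table")


#: ClaI, the enzyme whose site polymorphism separates the three paralogs
#: in the motivating assay.
CLAI = EnzymeSpec("ClaI", "ATCGAT", 2)
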