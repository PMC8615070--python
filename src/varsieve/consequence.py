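"""Coding-sequence consequence engine.

Parses coding-DNA (HGVS ``c.``) notation for substitutions, deletions,
duplications, insertions and deletion-insertions, applies one or several
variants *simultaneously* against the original CDS coordinates, translates
with the standard genetic code, and diffs wild-type against mutant protein.

Coordinates are 1-based inclusive CDS positions; codon ``i`` spans
positions ``3i-2 .. 3i``.  Joint application walks the variants
right-to-left so earlier edits never shift the coordinates of later ones —
this is what makes "simultaneous deletion of GC and duplication of TT"
well defined.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DataError, ReferenceMismatchError, UnsupportedNotationError

log = logging.getLogger(__name__)

SUBSTITUTION = "substitution"
DELETION = "deletion"
DUPLICATION = "duplication"
INSERTION = "insertion"
DELINS = "delins"

_STOP = "*"

# Standard genetic code (NCBI table 1).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": _STOP, "TAG": _STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": _STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


@dataclass(frozen=True)
class CdsVariant:
    """A parsed coding variant with 1-based inclusive CDS coordinates.

    ``stated_ref`` is the allele the notation claims occupies
    ``[start, end]`` (empty when the notation omits it, and always empty
    for insertions); ``inserted`` is the incoming sequence (empty for pure
    deletions; equal to ``stated_ref`` for duplications when stated).
    """

    kind: str
    start: int
    end: int
    stated_ref: str = ""
    inserted: str = ""

    def __post_init__(self):
        if self.start < 1:
            raise DataError(f"CDS coordinates are 1-based, got start={self.start}")
        if self.end < self.start:
            raise DataError(f"inverted range {self.start}_{self.end}")
        if self.kind == DUPLICATION and self.stated_ref and self.inserted != self.stated_ref:
            raise DataError("duplication must insert a copy of its own reference span")

    @property
    def net_length_change(self) -> int:
        """Inserted minus deleted bases (duplication deletes nothing)."""
        span = self.end - self.start + 1
        if self.kind == SUBSTITUTION:
            return 0
        if self.kind == DELETION:
            return -span
        if self.kind in (DUPLICATION, INSERTION):
            return span if self.kind == DUPLICATION else len(self.inserted)
        return len(self.inserted) - span  # delins


_HGVS_RE = re.compile(
    r"""^c\.
        (?:
            (?P<sub_pos>\d+)(?P<sub_ref>[ACGT])>(?P<sub_alt>[ACGT])
          | (?P<s>\d+)(?:_(?P<e>\d+))?
            (?:
                del(?P<del_seq>[ACGT]*)(?:ins(?P<delins_seq>[ACGT]+))?
              | dup(?P<dup_seq>[ACGT]*)
              | ins(?P<ins_seq>[ACGT]+)
            )
        )$""",
    re.VERBOSE | re.IGNORECASE,
)

_UNSUPPORTED_MARKERS = ("+", "-", "*", "?", "[", "(")


def parse_hgvs_c(notation: str) -> CdsVariant:
    """Parse a coding-variant notation string into a :class:`CdsVariant`.

    Supported grammar: ``c.<pos><ref>><alt>``, ``c.<s>[_<e>]del[SEQ]``,
    ``c.<s>[_<e>]dup[SEQ]``, ``c.<s>_<e>ins<SEQ>``,
    ``c.<s>[_<e>]del[SEQ]ins<SEQ>``.  Internal whitespace is tolerated.
    Intronic offsets, UTR (``*``) positions and more exotic constructs
    raise :class:`UnsupportedNotationError`.
    """
    compact = re.sub(r"\s+", "", notation)
    body = compact[2:] if compact.startswith("c.") else compact
    if any(m in body for m in _UNSUPPORTED_MARKERS):
        raise UnsupportedNotationError(
            f"{notation!r}: intronic/UTR offsets and complex alleles are not supported"
        )
    m = _HGVS_RE.match(compact)
    if not m:
        raise UnsupportedNotationError(f"cannot parse coding-variant notation {notation!r}")

    def grab(group: str) -> str | None:
        s = m.group(group)
        return s.upper() if s is not None else None

    if m.group("sub_pos"):
        pos = int(m.group("sub_pos"))
        return CdsVariant(SUBSTITUTION, pos, pos,
                          stated_ref=grab("sub_ref"), inserted=grab("sub_alt"))

    start = int(m.group("s"))
    end = int(m.group("e")) if m.group("e") else start
    if end < start:
        raise DataError(f"{notation!r}: inverted range {start}_{end}")

    if grab("ins_seq") is not None:
        if end != start + 1:
            raise UnsupportedNotationError(
                f"{notation!r}: insertion requires two flanking positions s_s+1"
            )
        return CdsVariant(INSERTION, start, end, inserted=grab("ins_seq"))
    if grab("dup_seq") is not None:
        dup = grab("dup_seq")
        if dup and len(dup) != end - start + 1:
            raise DataError(
                f"{notation!r}: stated sequence length {len(dup)} != span {end - start + 1}"
            )
        return CdsVariant(DUPLICATION, start, end, stated_ref=dup, inserted=dup)
    # del or delins
    deleted = grab("del_seq") or ""
    if deleted and len(deleted) != end - start + 1:
        raise DataError(
            f"{notation!r}: stated sequence length {len(deleted)} != span {end - start + 1}"
        )
    if grab("delins_seq") is not None:
        return CdsVariant(DELINS, start, end, stated_ref=deleted, inserted=grab("delins_seq"))
    return CdsVariant(DELETION, start, end, stated_ref=deleted)


def _check_ref(cds: str, v: CdsVariant) -> None:
    found = cds[v.start - 1 : v.end]
    if v.kind == INSERTION:
        return  # insertion states no reference bases
    if len(found) < v.end - v.start + 1:
        raise DataError(f"variant span {v.start}_{v.end} beyond CDS length {len(cds)}")
    if v.stated_ref and found != v.stated_ref:
        raise ReferenceMismatchError(v.start, v.stated_ref, found)


def apply_variants(
    cds: str,
    variants: Sequence[CdsVariant],
    check_ref: bool = True,
) -> str:
    """Apply variants jointly against the original CDS coordinates.

    Variants must be non-overlapping; they are applied right-to-left so
    every edit sees its original coordinates.  Duplications insert a copy
    of ``[start, end]`` immediately after ``end``; insertions place the
    incoming bases between their two flanking positions.  With
    ``check_ref`` (default) any stated reference allele must match the CDS
    or a :class:`ReferenceMismatchError` is raised.
    """
    cds = cds.upper()
    if set(cds) - set("ACGT"):
        raise DataError("CDS contains non-ACGT characters")
    if len(cds) % 3 != 0:
        log.warning("CDS length %d is not a multiple of 3", len(cds))
    if not cds.startswith("ATG"):
        log.warning("CDS does not start with ATG")

    # overlap check on the occupied spans (insertions occupy the zero-width
    # boundary between start and end)
    spans = []
    for v in variants:
        if v.end > len(cds):
            raise DataError(f"variant span {v.start}_{v.end} beyond CDS length {len(cds)}")
        spans.append((v.start, v.end, v) if v.kind != INSERTION else (v.start + 1, v.start, v))
    spans.sort(key=lambda t: (t[0], t[1]))
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise DataError(f"overlapping variants at positions {s1}_{e1} and {s2}_{e2}")

    if check_ref:
        for v in variants:
            _check_ref(cds, v)

    out = cds
    for v in sorted(variants, key=lambda v: v.start, reverse=True):
        if v.kind == SUBSTITUTION:
            out = out[: v.start - 1] + v.inserted + out[v.end :]
        elif v.kind == DELETION:
            out = out[: v.start - 1] + out[v.end :]
        elif v.kind == DUPLICATION:
            out = out[: v.end] + cds[v.start - 1 : v.end] + out[v.end :]
        elif v.kind == INSERTION:
            out = out[: v.start] + v.inserted + out[v.start :]
        elif v.kind == DELINS:
            out = out[: v.start - 1] + v.inserted + out[v.end :]
        else:
            raise DataError(f"unknown variant kind {v.kind!r}")
    return out


def translate(cds: str) -> str:
    """Standard-code translation, stopping at the first stop codon.

    A trailing partial codon is ignored with a warning; non-ACGT input is
    an error.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise DataError(f"sequence too short to translate ({len(cds)} nt)")
    if set(cds) - set("ACGT"):
        bad = sorted(set(cds) - set("ACGT"))
        raise DataError(f"cannot translate: non-ACGT characters {bad}")
    if len(cds) % 3:
        log.warning("trailing partial codon (%d nt) ignored", len(cds) % 3)
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i : i + 3]]
        if aa == _STOP:
            break
        protein.append(aa)
    return "".join(protein)


@dataclass(frozen=True)
class ProteinDiff:
    """Protein-level summary of a CDS edit.

    ``substitutions`` are (1-based residue, wild-type aa, mutant aa) in
    increasing position; ``frameshift_at`` is the first differing residue
    when the caller-supplied nucleotide length change is not a multiple of
    3; ``length_change`` is in codons (mutant minus wild type).
    """

    substitutions: tuple
    frameshift_at: int | None = None
    stop_gained_at: int | None = None
    stop_lost: bool = False
    length_change: int = 0

    @property
    def summary(self) -> str:
        parts = [f"p.{wt}{i}{mut}" for i, wt, mut in self.substitutions]
        if self.frameshift_at is not None:
            parts.append(f"p.fs@{self.frameshift_at}")
        if self.stop_gained_at is not None:
            parts.append(f"p.*@{self.stop_gained_at}")
        if self.stop_lost:
            parts.append("stop_lost")
        return "; ".join(parts) if parts else "no protein change"


def diff_proteins(wt: str, mut: str, cds_length_change: int = 0) -> ProteinDiff:
    """Positional comparison of wild-type and mutant protein strings.

    Substitutions are collected up to the shorter length.  The caller
    supplies the CDS-level net base change; a value not divisible by 3
    flags a frameshift at the first differing residue.  A mutant shorter
    than the expected length indicates a gained stop; a longer one under a
    frame-preserving change indicates a lost stop or inframe growth.
    """
    subs = tuple(
        (i + 1, a, b) for i, (a, b) in enumerate(zip(wt, mut)) if a != b
    )
    first_diff = subs[0][0] if subs else min(len(wt), len(mut)) + 1
    frameshift_at = first_diff if cds_length_change % 3 != 0 else None
    expected_mut_len = len(wt) + (cds_length_change // 3 if cds_length_change % 3 == 0 else 0)
    stop_gained_at = len(mut) + 1 if len(mut) < expected_mut_len else None
    stop_lost = cds_length_change % 3 == 0 and len(mut) > expected_mut_len
    return ProteinDiff(
        substitutions=subs,
        frameshift_at=frameshift_at,
        stop_gained_at=stop_gained_at,
        stop_lost=stop_lost,
        length_change=len(mut) - len(wt),
    )


def predict_effect(cds: str, variants: Sequence[CdsVariant], check_ref: bool = True) -> ProteinDiff:
    """Apply, translate and diff in one call."""
    mutated = apply_variants(cds, variants, check_ref=check_ref)
    net = sum(v.net_length_change for v in variants)
    return diff_proteins(translate(cds), translate(mutated), cds_length_change=net)


def build_cds(n_codons: int, codon_overrides: Mapping[int, str] | None = None,
              filler: str = "AAA") -> str:
    """Construct a synthetic in-frame CDS: ATG start, filler codons, overrides.

    ``codon_overrides`` maps 1-based codon indices to codon strings;
    index 1 defaults to ATG.  Useful to reconstruct a minimal sequence
    context around residues of interest when the real transcript is not at
    hand (e.g. codons 395-396 = GCT GTT, the unique assignment under which
    a GC deletion at 1183-1184 plus a TT duplication at 1187-1188 yields
    Cys395 + Phe396).
    """
    if n_codons < 1:
        raise DataError("CDS needs at least one codon")
    overrides = dict(codon_overrides or {})
    codons = []
    for i in range(1, n_codons + 1):
        codon = overrides.get(i, "ATG" if i == 1 else filler)
        codon = codon.upper()
        if len(codon) != 3 or set(codon) - set("ACGT"):
            raise DataError(f"codon override {i}: {codon!r} is not a valid codon")
        if i < n_codons and CODON_TABLE[codon] == _STOP:
            raise DataError(f"codon override {i} is an internal stop codon")
        codons.append(codon)
    return "".join(codons)
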