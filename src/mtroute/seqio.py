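"""rCRS-relative haplotype notation, sequences and file formats.

Human mtDNA variation is conventionally reported relative to the revised
Cambridge Reference Sequence (rCRS), a 16,569-bp circular genome with a
historical placeholder at position 3107.  A haplotype is the list of
positions at which a sample differs from the rCRS, written in the compact
notation used throughout the mtDNA literature:

* ``16223``     transition at 16223 (derived base implied by the reference);
* ``95C``       transversion to C at position 95 (transversions always carry
  the derived base);
* ``16189.1C``  insertion of a C after position 16189 (first inserted base);
* ``8281d``     deletion of the base at 8281;
* ``16223!``    back-mutation marker used in haplogroup motifs: the site has
  reverted to the rCRS state.

This module owns the :class:`Variant`, :class:`MtHaplotype` and
:class:`GeoPoint` value types, the token grammar, haplotype<->sequence
conversion against a reference (pairwise global alignment, substitutions
preferred over indels, indel ties broken toward the rightmost placement in
homopolymer runs), and readers/writers for the haplotype TSV and FASTA
formats the pipeline touches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    ContractViolation,
    PositionRangeError,
    SchemaError,
    ValidationError,
    VariantParseError,
)

RCRS_LENGTH = 16569
PLACEHOLDER_POSITION = 3107

#: transition partners (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: sites conventionally excluded from classification and network building:
#: hypermutable control-region positions plus length variation in the
#: 16184-16193 poly-C tract.
HYPERMUTABLE_POSITIONS = frozenset({16182, 16183, 16519})
POLY_C_TRACT = (16184, 16193)

_TOKEN_RE = re.compile(r"^(\d+)(?:\.(\d+))?([ACGTacgt]*|d)(!?)$")


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-relative change: the atom of mtDNA haplotype notation.

    Equality and ordering are over ``(position, suffix_index, kind,
    derived_state, back)``; a bare transition (empty ``derived_state``)
    is distinct from one with the derived base spelled out — use
    :meth:`normalize` to resolve bases against a reference before
    comparing call sets.
    """

    position: int
    kind: str  # 'transition' | 'transversion' | 'insertion' | 'deletion'
    derived_state: str = ""
    suffix_index: int = 0
    back: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise PositionRangeError(
                f"position {self.position} outside rCRS range 1..{RCRS_LENGTH}"
            )
        if self.kind not in ("transition", "transversion", "insertion", "deletion"):
            raise ValidationError(f"unknown variant kind {self.kind!r}")
        if self.kind == "transversion" and not self.derived_state:
            raise ValidationError(
                f"transversion at {self.position} must carry an explicit derived base"
            )
        if self.kind == "insertion":
            if not self.derived_state:
                raise ValidationError(f"insertion at {self.position} lacks inserted bases")
            if self.suffix_index < 1:
                raise ValidationError(
                    f"insertion at {self.position} needs a suffix index >= 1"
                )
        if self.kind == "deletion" and self.derived_state:
            raise ValidationError(f"deletion at {self.position} must not carry a base")

    @property
    def is_substitution(self) -> bool:
        return self.kind in ("transition", "transversion")

    def normalize(self, ref: str) -> "Variant":
        """Return a copy with the derived base resolved against *ref*.

        Only bare transitions change: their derived state becomes the
        transition partner of the reference base.
        """
        if self.kind == "transition" and not self.derived_state:
            base = ref[self.position - 1].upper()
            if base not in TRANSITIONS:
                raise ValidationError(
                    f"reference base {base!r} at {self.position} has no transition partner"
                )
            return replace(self, derived_state=TRANSITIONS[base])
        return self

    def is_hypermutable(self) -> bool:
        """True for conventionally ignored sites (see module docstring)."""
        if self.position in HYPERMUTABLE_POSITIONS:
            return True
        lo, hi = POLY_C_TRACT
        return lo <= self.position <= hi and self.kind in ("insertion", "deletion")


def parse_variant_string(token: str, ref: str | None = None) -> Variant:
    """Parse one rCRS-relative variant token.

    Without a reference the notation convention decides the kind: a bare
    position is a transition, an explicit base marks a transversion.  With
    *ref* supplied, an explicit base is compared to the reference base and
    classified as transition or transversion accordingly.
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None or not m.group(1):
        raise VariantParseError(f"malformed variant token {token!r}")
    position = int(m.group(1))
    if not 1 <= position <= RCRS_LENGTH:
        raise PositionRangeError(
            f"position {position} in token {token!r} outside rCRS range 1..{RCRS_LENGTH}"
        )
    has_suffix = m.group(2) is not None
    suffix = int(m.group(2)) if has_suffix else 0
    body = m.group(3)
    back = bool(m.group(4))

    if body == "d":
        if has_suffix:
            raise VariantParseError(f"deletion token {token!r} cannot carry a suffix index")
        return Variant(position, "deletion", back=back)
    bases = body.upper()
    if has_suffix:
        if not bases or suffix < 1:
            raise VariantParseError(f"malformed insertion token {token!r}")
        return Variant(position, "insertion", bases, suffix, back=back)
    if not bases:
        return Variant(position, "transition", back=back)
    if len(bases) > 1:
        raise VariantParseError(f"substitution token {token!r} carries more than one base")
    if ref is not None:
        ref_base = ref[position - 1].upper()
        if bases == ref_base:
            raise VariantParseError(
                f"token {token!r}: derived base equals the reference base"
            )
        if TRANSITIONS.get(ref_base) == bases:
            return Variant(position, "transition", bases, back=back)
        return Variant(position, "transversion", bases, back=back)
    # Notation convention: transitions may omit the base, transversions
    # always spell it out, so an explicit base means transversion.
    return Variant(position, "transversion", bases, back=back)


def format_variant(v: Variant) -> str:
    """Inverse of :func:`parse_variant_string` on well-formed tokens."""
    bang = "!" if v.back else ""
    if v.kind == "deletion":
        return f"{v.position}d{bang}"
    if v.kind == "insertion":
        return f"{v.position}.{v.suffix_index}{v.derived_state}{bang}"
    if v.kind == "transition" and not v.derived_state:
        return f"{v.position}{bang}"
    if v.kind == "transition":
        # keep bare notation for transitions so formatting stays injective
        return f"{v.position}{bang}"
    return f"{v.position}{v.derived_state}{bang}"


@dataclass(frozen=True)
class GeoPoint:
    """Geographic point in decimal degrees, north/east positive."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")


_ANGLE_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:[°º]\s*(\d+(?:\.\d+)?)\s*[´'′]?)?\s*([NSEWnsew])\s*$"
)


def parse_angle(text: str) -> tuple[float, str]:
    """Parse one degree(-minute) angle like ``12°23´N`` or ``43.35E``.

    Returns (decimal degrees with south/west negative, axis 'lat'|'lon').
    """
    m = _ANGLE_RE.match(text)
    if m is None:
        raise ValidationError(f"cannot parse coordinate {text!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2)) if m.group(2) else 0.0
    hemi = m.group(3).upper()
    value = deg + minutes / 60.0
    if hemi in "SW":
        value = -value
    return value, ("lat" if hemi in "NS" else "lon")


def parse_coordinates(text: str) -> GeoPoint:
    """Parse a paired coordinate string like ``12°23´N-43°21´E``."""
    parts = re.split(r"\s*-\s*(?=[^NSEW]*[NSEWnsew]\s*$)", text.strip(), maxsplit=1)
    if len(parts) != 2:
        raise ValidationError(f"cannot parse coordinate pair {text!r}")
    lat = lon = None
    for part in parts:
        value, axis = parse_angle(part)
        if axis == "lat":
            lat = value
        else:
            lon = value
    if lat is None or lon is None:
        raise ValidationError(f"coordinate pair {text!r} lacks a latitude or longitude")
    return GeoPoint(lat, lon)


Interval = tuple[int, int]


def parse_region(text: str) -> tuple[Interval, ...]:
    """Parse covered intervals like ``16024-16383;57-372`` (1-based, inclusive)."""
    intervals: list[Interval] = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = re.match(r"^(\d+)\s*-\s*(\d+)$", chunk)
        if m is None:
            raise SchemaError(f"cannot parse region chunk {chunk!r}")
        lo, hi = int(m.group(1)), int(m.group(2))
        if not (1 <= lo <= hi <= RCRS_LENGTH):
            raise SchemaError(f"region {chunk!r} outside rCRS coordinates")
        intervals.append((lo, hi))
    if not intervals:
        raise SchemaError(f"empty region specification {text!r}")
    return tuple(sorted(intervals))


def format_region(region: Sequence[Interval]) -> str:
    return ";".join(f"{lo}-{hi}" for lo, hi in region)


FULL_GENOME: tuple[Interval, ...] = ((1, RCRS_LENGTH),)


@dataclass(frozen=True)
class MtHaplotype:
    """One sample: its rCRS-relative variants, coverage, origin and label."""

    sample_id: str
    variants: tuple[Variant, ...] = ()
    region: tuple[Interval, ...] = FULL_GENOME
    origin: GeoPoint | None = None
    population: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(set(self.variants)))
        object.__setattr__(self, "variants", ordered)
        seen: dict[tuple[int, int], Variant] = {}
        for v in ordered:
            key = (v.position, v.suffix_index)
            if key in seen and seen[key] != v:
                raise ValidationError(
                    f"{self.sample_id}: conflicting states at position "
                    f"{v.position}.{v.suffix_index}: "
                    f"{format_variant(seen[key])} vs {format_variant(v)}"
                )
            seen[key] = v
            if not self.covers(v.position):
                raise ValidationError(
                    f"{self.sample_id}: variant {format_variant(v)} outside covered "
                    f"region {format_region(self.region)}"
                )

    def covers(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.region)

    def variant_set(self, exclude_hypermutable: bool = False) -> frozenset[Variant]:
        if exclude_hypermutable:
            return frozenset(v for v in self.variants if not v.is_hypermutable())
        return frozenset(self.variants)

    def normalize(self, ref: str) -> "MtHaplotype":
        return replace(self, variants=tuple(v.normalize(ref) for v in self.variants))


# ---------------------------------------------------------------------------
# reference handling


def load_reference(path: str | Path | None = None) -> str:
    """Return the reference sequence as an upper-case string.

    With no *path* the packaged synthetic stand-in reference is used: a
    seeded random 16,569-bp sequence on rCRS coordinates (placeholder N at
    3107).  Pass the real rCRS FASTA for work on published haplotypes.
    """
    if path is None:
        source = resources.files("mtroute.data") / "rcrs_synthetic.fasta"
        with resources.as_file(source) as p:
            record = next(SeqIO.parse(str(p), "fasta"))
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    if len(seq) != RCRS_LENGTH:
        raise ValidationError(
            f"reference length {len(seq)} != {RCRS_LENGTH}; not on rCRS coordinates"
        )
    return seq


# ---------------------------------------------------------------------------
# haplotype <-> sequence


def _interval_of(interval: Interval) -> tuple[int, int]:
    lo, hi = interval
    if not (1 <= lo <= hi <= RCRS_LENGTH):
        raise ContractViolation(f"interval {interval} outside rCRS coordinates")
    return lo, hi


def haplotype_to_sequence(h: MtHaplotype, ref: str, interval: Interval) -> str:
    """Apply the haplotype's variants to *ref* over *interval*.

    Insertions lengthen and deletions shorten the returned string; the
    result is what a sequencer would read off this sample over the
    interval.
    """
    lo, hi = _interval_of(interval)
    if not any(rlo <= lo and hi <= rhi for rlo, rhi in h.region):
        raise ContractViolation(
            f"interval {interval} not inside covered region {format_region(h.region)}"
        )
    subs: dict[int, Variant] = {}
    dels: set[int] = set()
    ins: dict[int, list[Variant]] = {}
    for v in h.variants:
        if not lo <= v.position <= hi:
            raise ContractViolation(f"variant {format_variant(v)} outside interval")
        if v.is_substitution:
            subs[v.position] = v
        elif v.kind == "deletion":
            dels.add(v.position)
        else:
            ins.setdefault(v.position, []).append(v)
    out: list[str] = []
    for pos in range(lo, hi + 1):
        if pos in dels:
            pass
        elif pos in subs:
            v = subs[pos].normalize(ref)
            out.append(v.derived_state)
        else:
            out.append(ref[pos - 1])
        for v in sorted(ins.get(pos, []), key=lambda x: x.suffix_index):
            out.append(v.derived_state)
    return "".join(out)


def _banded_nw(ref_seg: str, seq: str, band: int) -> list[tuple[str, int, int]]:
    """Global alignment, substitution cost 1, gap cost 2, N matches free.

    Returns the traceback as a list of ops ('M'|'D'|'I', i, j) over 0-based
    indices into *ref_seg*/*seq*; ties are broken so gaps sit rightmost.
    """
    n, m = len(ref_seg), len(seq)
    lo = min(0, m - n) - band
    hi = max(0, m - n) + band
    width = hi - lo + 1
    INF = 1e18
    a = np.frombuffer(ref_seg.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    ncode = ord("N")

    D = np.full((n + 1, width), INF)
    ks = np.arange(lo, hi + 1)
    # row 0: D[0, j] = 2*j for j in band
    j0 = ks
    valid0 = (j0 >= 0) & (j0 <= m)
    D[0, valid0] = 2.0 * j0[valid0]
    shift_pen = 2.0 * np.arange(width)
    for i in range(1, n + 1):
        js = i + ks
        valid = (js >= 0) & (js <= m)
        prev = D[i - 1]
        # diagonal: (i-1, j-1) is the same band index in the previous row
        sub = np.full(width, INF)
        jpos = js - 1
        dv = valid & (jpos >= 0) & (jpos < m)
        idx = np.where(dv)[0]
        if idx.size:
            mism = (a[i - 1] != b[jpos[idx]]) & (a[i - 1] != ncode) & (b[jpos[idx]] != ncode)
            cost_idx = mism.astype(float)
            sub[idx] = prev[idx] + cost_idx
        # vertical (deletion): (i-1, j) is band index k+1 in the previous row
        up = np.full(width, INF)
        up[:-1] = prev[1:] + 2.0
        best = np.minimum(sub, up)
        # horizontal (insertion) resolved by a prefix-min scan within the row:
        # row[k] = min_{k'<=k} best[k'] + 2*(k-k')
        row = np.minimum.accumulate(best - shift_pen) + shift_pen
        row[~valid] = INF
        D[i] = row
    # traceback
    ops: list[tuple[str, int, int]] = []
    i, j = n, m
    k_end = m - n - lo
    if not (0 <= k_end < width) or D[n, k_end] >= INF / 2:
        raise AlignmentError("alignment fell outside the band; increase max_band")

    def cell(ii: int, jj: int) -> float:
        k = jj - ii - lo
        if 0 <= k < width and 0 <= jj <= m:
            return D[ii, k]
        return INF

    while i > 0 or j > 0:
        cur = cell(i, j)
        # prefer gap moves at ties: walks encountered right-to-left, so this
        # places tied gaps rightmost within homopolymer runs
        if j > 0 and abs(cell(i, j - 1) + 2.0 - cur) < 1e-9:
            ops.append(("I", i, j - 1))
            j -= 1
            continue
        if i > 0 and abs(cell(i - 1, j) + 2.0 - cur) < 1e-9:
            ops.append(("D", i - 1, j))
            i -= 1
            continue
        if i > 0 and j > 0:
            mism = (
                a[i - 1] != b[j - 1]
                and a[i - 1] != ncode
                and b[j - 1] != ncode
            )
            if abs(cell(i - 1, j - 1) + float(mism) - cur) < 1e-9:
                ops.append(("M", i - 1, j - 1))
                i -= 1
                j -= 1
                continue
        raise AlignmentError("traceback failed; inconsistent DP table")
    ops.reverse()
    return ops


def sequence_to_haplotype(
    seq: str,
    ref: str,
    interval: Interval,
    sample_id: str = "",
    max_band: int = 32,
    population: str = "",
    origin: GeoPoint | None = None,
) -> MtHaplotype:
    """Call the minimal rCRS-relative variant list for *seq* over *interval*.

    Pairwise global alignment against the reference slice with substitution
    cost 1 and gap cost 2, so substitutions are preferred over indels;
    equal-cost indel placements resolve to the rightmost position.  The
    band half-width *max_band* bounds the tolerated edit distance.
    """
    lo, hi = _interval_of(interval)
    ref_seg = ref[lo - 1 : hi]
    if abs(len(seq) - len(ref_seg)) > max_band:
        raise AlignmentError(
            f"length difference {abs(len(seq) - len(ref_seg))} exceeds band {max_band}"
        )
    ops = _banded_nw(ref_seg, seq, max_band)
    variants: list[Variant] = []
    last_ref_pos = lo - 1  # rCRS coordinate of the last consumed reference base
    ins_run = 0
    for op, i, j in ops:
        if op == "M":
            last_ref_pos = lo + i
            ins_run = 0
            rbase, qbase = ref_seg[i].upper(), seq[j].upper()
            if rbase != qbase and rbase != "N" and qbase != "N":
                kind = "transition" if TRANSITIONS.get(rbase) == qbase else "transversion"
                variants.append(Variant(lo + i, kind, qbase))
        elif op == "D":
            last_ref_pos = lo + i
            ins_run = 0
            variants.append(Variant(lo + i, "deletion"))
        else:  # insertion relative to the reference
            ins_run += 1
            anchor = max(last_ref_pos, lo)  # insertions before the window anchor at its start
            variants.append(Variant(anchor, "insertion", seq[j].upper(), ins_run))
    return MtHaplotype(
        sample_id=sample_id,
        variants=tuple(variants),
        region=(interval,),
        origin=origin,
        population=population,
    )


# ---------------------------------------------------------------------------
# tabular and FASTA I/O

REQUIRED_COLUMNS = ("sample_id", "population", "latitude", "longitude", "region", "variants")


def _parse_coord_cell(cell: object, axis: str) -> float | None:
    if cell is None:
        return None
    text = str(cell).strip()
    if not text or text.lower() in ("nan", "na", "unknown", "?"):
        return None
    try:
        return float(text)
    except ValueError:
        value, parsed_axis = parse_angle(text)
        if parsed_axis != axis:
            raise SchemaError(f"{axis} column holds a {parsed_axis} value: {cell!r}")
        return value


def read_haplotype_table(path: str | Path) -> list[MtHaplotype]:
    """Read the haplotype TSV (see REQUIRED_COLUMNS for the schema).

    Coordinates may be decimal degrees or degree-minute strings; empty
    coordinates yield an unknown origin.  Variant tokens are
    space-separated; an empty cell means the rCRS state over the region.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    haplotypes: list[MtHaplotype] = []
    for row in df.itertuples(index=False):
        lat = _parse_coord_cell(row.latitude, "lat")
        lon = _parse_coord_cell(row.longitude, "lon")
        origin = GeoPoint(lat, lon) if lat is not None and lon is not None else None
        tokens = [t for t in str(row.variants).split() if t]
        variants = tuple(parse_variant_string(t) for t in tokens)
        haplotypes.append(
            MtHaplotype(
                sample_id=str(row.sample_id),
                variants=variants,
                region=parse_region(row.region),
                origin=origin,
                population=str(row.population),
            )
        )
    return haplotypes


def write_haplotype_table(haplotypes: Iterable[MtHaplotype], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for h in haplotypes:
        rows.append(
            {
                "sample_id": h.sample_id,
                "population": h.population,
                "latitude": f"{h.origin.latitude:.6f}" if h.origin else "",
                "longitude": f"{h.origin.longitude:.6f}" if h.origin else "",
                "region": format_region(h.region),
                "variants": " ".join(format_variant(v) for v in h.variants),
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )
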