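"""Strain pseudogenomes, invertible coordinate maps, and allele-specific reads.

A pseudogenome is the reference sequence with one strain's SNP and short-indel
alleles spliced in.  Because indels change sequence length, every pseudogenome
carries a :class:`CoordinateMap` that converts positions between the reference
frame and the strain frame in both directions.  Reads are assigned to an allele
by the perfect-match spanning-variant rule: a read belongs to haplotype X iff
it matches X's sequence exactly over its span, that span covers at least one
position where the two haplotypes differ, and it does not also match the other
haplotype over the homologous span.

Internal coordinates are 0-based half-open; VCF input/output is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "strain"]


class VariantTable:
    """Per-strain SNP/indel records anchored to 1-based reference coordinates.

    Wraps a DataFrame with columns ``chrom, pos, ref, alt, strain``.  Records
    are kept sorted by (chrom, pos); overlapping records on the reference are
    rejected, as are alleles outside the {A,C,G,T} alphabet.
    """

    def __init__(self, records: pd.DataFrame | Iterable[tuple] | None = None):
        if records is None:
            df = pd.DataFrame(columns=VARIANT_COLUMNS)
        elif isinstance(records, pd.DataFrame):
            df = records.loc[:, VARIANT_COLUMNS].copy()
        else:
            df = pd.DataFrame(list(records), columns=VARIANT_COLUMNS)
        if len(df):
            df["pos"] = df["pos"].astype(int)
            df["ref"] = df["ref"].astype(str).str.upper()
            df["alt"] = df["alt"].astype(str).str.upper()
            bad = ~(df["ref"].map(_is_dna) & df["alt"].map(_is_dna))
            if bad.any():
                raise ValueError(
                    f"non-ACGT allele in variant records: {df.loc[bad].head().to_dict('records')}"
                )
            if (df["ref"] == df["alt"]).any():
                raise ValueError("ref and alt alleles must differ")
            df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
            for chrom, sub in df.groupby("chrom", sort=False):
                ends = sub["pos"].to_numpy() + sub["ref"].str.len().to_numpy() - 1
                if (sub["pos"].to_numpy()[1:] <= ends[:-1]).any():
                    raise ValueError(f"overlapping variant records on {chrom}")
        self.df = df
        # per-chrom sorted footprint arrays, cached for fast interval queries
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            v_start = sub["pos"].to_numpy() - 1
            v_end = v_start + sub["ref"].str.len().to_numpy()
            self._index[str(chrom)] = (v_start, np.maximum.accumulate(v_end))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, VariantTable) and self.df.equals(other.df)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of records whose reference footprint intersects [start, end) (0-based)."""
        if chrom not in self._index:
            return 0
        v_start, v_end_cum = self._index[chrom]
        # records are non-overlapping and sorted, so footprints are sorted too
        lo = int(np.searchsorted(v_end_cum, start, side="right"))
        hi = int(np.searchsorted(v_start, end, side="left"))
        return max(hi - lo, 0)


def _is_dna(s: str) -> bool:
    return len(s) > 0 and set(s) <= VALID_BASES


@dataclass
class PseudoGenome:
    """One strain's genome sequence plus provenance."""

    strain: str
    source: str
    seqs: dict = field(default_factory=dict)  # chrom -> str

    def __getitem__(self, chrom: str) -> str:
        return self.seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])


class _ChromMap:
    """Piecewise-constant offset map for one chromosome (all arrays 0-based)."""

    __slots__ = ("ref_start", "ref_len", "strain_start", "alt_len", "off_after")

    def __init__(self, ref_start, ref_len, strain_start, alt_len):
        self.ref_start = np.asarray(ref_start, dtype=np.int64)
        self.ref_len = np.asarray(ref_len, dtype=np.int64)
        self.strain_start = np.asarray(strain_start, dtype=np.int64)
        self.alt_len = np.asarray(alt_len, dtype=np.int64)
        self.off_after = self.strain_start + self.alt_len - (self.ref_start + self.ref_len)

    def _map(self, pos, starts, lens, other_starts, other_lens, offs):
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return int(pos), False
        if pos >= starts[i] + lens[i]:
            return int(pos + offs[i]), False
        d = pos - starts[i]
        if d < other_lens[i]:
            return int(other_starts[i] + d), False
        # deleted in the target frame: snap to nearest left anchor
        return int(other_starts[i] + other_lens[i] - 1), True

    def ref_to_strain(self, pos: int) -> tuple[int, bool]:
        return self._map(pos, self.ref_start, self.ref_len, self.strain_start, self.alt_len, self.off_after)

    def strain_to_ref(self, pos: int) -> tuple[int, bool]:
        return self._map(pos, self.strain_start, self.alt_len, self.ref_start, self.ref_len, -self.off_after)


class CoordinateMap:
    """Invertible reference <-> strain position mapping for one pseudogenome.

    Positions that fall in sequence deleted from the target frame are snapped
    to the nearest anchor on their left and flagged.  On all other positions
    the map is strictly monotone and round-trips exactly.
    """

    def __init__(self, chrom_maps: dict[str, _ChromMap]):
        self._maps = chrom_maps

    @classmethod
    def identity(cls, chroms: Iterable[str]) -> "CoordinateMap":
        return cls({c: _ChromMap([], [], [], []) for c in chroms})

    @property
    def chroms(self):
        return self._maps.keys()

    def _get(self, chrom: str) -> _ChromMap:
        if chrom not in self._maps:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._maps[chrom]

    def ref_to_strain(self, chrom: str, pos: int) -> tuple[int, bool]:
        """Map a 0-based reference position into the strain frame -> (pos, deleted_flag)."""
        return self._get(chrom).ref_to_strain(pos)

    def strain_to_ref(self, chrom: str, pos: int) -> tuple[int, bool]:
        """Map a 0-based strain position into the reference frame -> (pos, deleted_flag)."""
        return self._get(chrom).strain_to_ref(pos)


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int  # half-open


def build_pseudogenome(
    reference: dict[str, str], variants: VariantTable, strain: str | None = None,
    source: str = "reference",
) -> tuple[PseudoGenome, CoordinateMap]:
    """Splice a strain's variants into the reference.

    Every record's ref allele is checked against the reference sequence at its
    position; a mismatch raises ``ValueError`` naming chrom:pos, since it
    signals a corrupt variant table.  Returns the strain genome and the
    coordinate map implied by the splices.  The length invariant
    ``len(pseudo) = len(ref) + sum(len(alt) - len(ref))`` holds exactly.
    """
    if strain is None:
        strains = variants.df["strain"].unique() if len(variants) else []
        strain = str(strains[0]) if len(strains) == 1 else "strain"
    seqs: dict[str, str] = {}
    chrom_maps: dict[str, _ChromMap] = {}
    for chrom, refseq in reference.items():
        refseq = refseq.upper()
        sub = variants.for_chrom(chrom)
        pieces: list[str] = []
        ref_starts, ref_lens, strain_starts, alt_lens = [], [], [], []
        cursor = 0  # reference frame
        out_len = 0
        for pos1, ref_a, alt_a in sub[["pos", "ref", "alt"]].itertuples(index=False):
            start = pos1 - 1
            if refseq[start : start + len(ref_a)] != ref_a:
                raise ValueError(
                    f"ref allele mismatch at {chrom}:{pos1}: expected {ref_a!r}, "
                    f"reference has {refseq[start:start + len(ref_a)]!r}"
                )
            pieces.append(refseq[cursor:start])
            out_len += start - cursor
            ref_starts.append(start)
            ref_lens.append(len(ref_a))
            strain_starts.append(out_len)
            alt_lens.append(len(alt_a))
            pieces.append(alt_a)
            out_len += len(alt_a)
            cursor = start + len(ref_a)
        pieces.append(refseq[cursor:])
        seqs[chrom] = "".join(pieces)
        chrom_maps[chrom] = _ChromMap(ref_starts, ref_lens, strain_starts, alt_lens)
    genome = PseudoGenome(strain=strain, source=source, seqs=seqs)
    return genome, CoordinateMap(chrom_maps)


def shift_interval(
    cmap: CoordinateMap, interval: Interval | tuple, direction: str
) -> tuple[Interval, bool]:
    """Shift a half-open interval between frames.

    ``direction`` is ``"to_strain"`` or ``"to_reference"``.  Endpoints landing
    in deleted sequence are snapped left; the returned flag is True if either
    endpoint was snapped.  Empty intervals are returned unchanged.
    """
    chrom, start, end = interval
    if direction == "to_strain":
        fn = cmap.ref_to_strain
    elif direction == "to_reference":
        fn = cmap.strain_to_ref
    else:
        raise ValueError(f"direction must be 'to_strain' or 'to_reference', got {direction!r}")
    if end <= start:
        return Interval(chrom, start, end), False
    s, flag_s = fn(chrom, start)
    e_last, flag_e = fn(chrom, end - 1)
    return Interval(chrom, s, e_last + 1), bool(flag_s or flag_e)


class AlleleAssignment(NamedTuple):
    read_id: str
    label: str  # "allele_A" | "allele_B" | "unassigned"
    n_variants_spanned: int


def assign_read_allele(
    read_seq: str,
    chrom: str,
    ref_start: int,
    genomes: dict[str, PseudoGenome],
    maps: dict[str, CoordinateMap],
    variants: dict[str, VariantTable],
    read_id: str = "",
    labels: tuple[str, str] = ("allele_A", "allele_B"),
) -> AlleleAssignment:
    """Assign one read to a haplotype by the perfect-match spanning-variant rule.

    Parameters
    ----------
    read_seq : str
        Read bases (uppercase).
    chrom, ref_start : str, int
        Mapped position of the read's 5' end in the reference frame (0-based).
    genomes, maps, variants : dict
        Keyed by the two strain names, in the order corresponding to `labels`.

    A read is assigned to strain X iff it matches X's sequence exactly over
    its span, that span covers >=1 position where the strains differ, and it
    does not match the other strain over the homologous span.  Reads matching
    both frames (possible near indel edges) or neither are unassigned.
    """
    strains = list(genomes)
    if len(strains) != 2:
        raise ValueError("exactly two strains required")
    L = len(read_seq)
    read_seq = read_seq.upper()

    match: dict[str, bool] = {}
    strain_pos: dict[str, int] = {}
    for s in strains:
        p, _deleted = maps[s].ref_to_strain(chrom, ref_start)
        strain_pos[s] = p
        seq = genomes[s][chrom]
        match[s] = 0 <= p and p + L <= len(seq) and seq[p : p + L] == read_seq

    n_matches = sum(match.values())
    if n_matches != 1:
        return AlleleAssignment(read_id, "unassigned", 0)

    x = strains[0] if match[strains[0]] else strains[1]
    y = strains[1] if x == strains[0] else strains[0]
    # reference footprint of the read, derived through the matching frame
    ref_end = maps[x].strain_to_ref(chrom, strain_pos[x] + L - 1)[0] + 1
    n_span = variants[x].count_overlapping(chrom, ref_start, ref_end) + variants[
        y
    ].count_overlapping(chrom, ref_start, ref_end)
    if n_span < 1:
        return AlleleAssignment(read_id, "unassigned", 0)
    # homologous span in the other frame must differ from the read
    y_start, _ = maps[y].ref_to_strain(chrom, ref_start)
    y_end = maps[y].ref_to_strain(chrom, ref_end - 1)[0] + 1
    homolog = genomes[y][chrom][y_start:y_end]
    if homolog == read_seq:
        return AlleleAssignment(read_id, "unassigned", n_span)
    label = labels[strains.index(x)]
    return AlleleAssignment(read_id, label, n_span)


def assign_reads(
    reads: pd.DataFrame,
    genomes: dict[str, PseudoGenome],
    maps: dict[str, CoordinateMap],
    variants: dict[str, VariantTable],
    labels: tuple[str, str] = ("allele_A", "allele_B"),
) -> pd.DataFrame:
    """Vector wrapper over :func:`assign_read_allele`.

    ``reads`` needs columns ``read_id, chrom, ref_start, seq``; returns a
    DataFrame with columns ``read_id, label, n_variants_spanned``.
    """
    out = [
        assign_read_allele(
            seq, chrom, int(start), genomes, maps, variants, read_id=rid, labels=labels
        )
        for rid, chrom, start, seq in reads[["read_id", "chrom", "ref_start", "seq"]].itertuples(
            index=False
        )
    ]
    return pd.DataFrame(out, columns=["read_id", "label", "n_variants_spanned"])


def extract_peak_sequences(
    genome: PseudoGenome,
    cmap: CoordinateMap,
    peaks: pd.DataFrame,
    width: int,
) -> dict[str, str]:
    """Fixed-width sequences centered on peak midpoints, in the strain frame.

    ``peaks`` needs columns ``peak_id, chrom, start, end`` (0-based half-open,
    reference frame).  Midpoints are lifted into the strain frame; peaks whose
    midpoint is deleted in the strain, or whose window runs off the sequence,
    are skipped with a warning.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out: dict[str, str] = {}
    for pid, chrom, start, end in peaks[["peak_id", "chrom", "start", "end"]].itertuples(
        index=False
    ):
        mid_ref = (int(start) + int(end)) // 2
        mid, deleted = cmap.ref_to_strain(chrom, mid_ref)
        if deleted:
            warnings.warn(f"peak {pid}: midpoint deleted in strain {genome.strain}; skipped")
            continue
        lo = mid - width // 2
        hi = lo + width
        seq = genome[chrom]
        if lo < 0 or hi > len(seq):
            warnings.warn(f"peak {pid}: window out of bounds in strain {genome.strain}; skipped")
            continue
        out[str(pid)] = seq[lo:hi]
    return out
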