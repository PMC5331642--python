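"""Reading crosslink sites, genomes and per-position feature tracks.

Every analysis window is a fixed 101-nt slice centred on a single-nucleotide
crosslink site.  Coordinates are 0-based half-open throughout; BED rows are
taken as printed.  On the minus strand the sequence is reverse-complemented
and all positional tracks reversed, so index 0 is always the 5'-most
transcript position.  T is normalised to U on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WINDOW_FLANK = 50
WINDOW_LEN = 2 * WINDOW_FLANK + 1  # 101

REGION_CATEGORIES = ("exon", "intron", "5'UTR", "3'UTR", "CDS")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

__all__ = [
    "WINDOW_LEN",
    "WINDOW_FLANK",
    "REGION_CATEGORIES",
    "Site",
    "Window",
    "read_sites",
    "extract_window",
    "reverse_complement",
    "read_matrix",
    "write_matrix",
    "load_benchmark_dir",
]


@dataclass(frozen=True)
class Site:
    """One labelled crosslink-centred genomic location."""

    chrom: str
    center: int  # 0-based genomic coordinate of the crosslink nucleotide
    strand: str
    label: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.center < WINDOW_FLANK:
            raise ValueError(
                f"center {self.center} too close to contig start: the "
                f"[-{WINDOW_FLANK},+{WINDOW_FLANK}] window would underflow"
            )


@dataclass
class Window:
    """All per-position tracks for one 101-nt crosslink window."""

    sequence: str
    region_labels: list[str] = field(default_factory=list)
    cobind_counts: np.ndarray | None = None  # 101 x E non-negative ints
    structure_probs: np.ndarray | None = None  # length 101 in [0, 1]

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LEN:
            raise ValueError(f"sequence length must be {WINDOW_LEN}, got {len(self.sequence)}")
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
        if self.region_labels and len(self.region_labels) != WINDOW_LEN:
            raise ValueError("region_labels length mismatch")
        if self.cobind_counts is not None:
            self.cobind_counts = np.asarray(self.cobind_counts)
            if self.cobind_counts.shape[0] != WINDOW_LEN:
                raise ValueError("cobind_counts must have 101 rows")
        if self.structure_probs is not None:
            self.structure_probs = np.asarray(self.structure_probs, dtype=float)
            if self.structure_probs.shape != (WINDOW_LEN,):
                raise ValueError("structure_probs must have length 101")
            if np.any((self.structure_probs < 0) | (self.structure_probs > 1)):
                raise ValueError("structure_probs must lie in [0, 1]")


def read_sites(path: str | Path) -> list[Site]:
    """Read crosslink sites from a BED-like file.

    Expects >= 4 whitespace/tab-delimited columns: chrom, start, end, label,
    with an optional 5th strand column (default ``+``).  Each interval is a
    1-bp crosslink site; ``center`` is its start coordinate.
    """
    sites: list[Site] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected >=4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start = int(parts[1])
                int(parts[2])
                label = int(parts[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed numeric field: {exc}") from None
            if label not in (0, 1):
                raise ValueError(f"line {lineno}: label must be 0 or 1, got {label}")
            strand = parts[4] if len(parts) > 4 else "+"
            try:
                sites.append(Site(chrom=chrom, center=start, strand=strand, label=label))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return sites


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string over A, C, G, U, N."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(
    site: Site,
    genome,
    region_labels: list[str] | None = None,
    cobind_counts: np.ndarray | None = None,
    structure_probs: np.ndarray | None = None,
) -> Window:
    """Slice the 101-nt window [center-50, center+51) around a site.

    ``genome`` is any mapping from chromosome name to a sliceable sequence
    (a ``pyfaidx.Fasta``, a ``dict`` of strings, ...).  Minus-strand windows
    are reverse-complemented and all supplied per-position tracks reversed.
    """
    try:
        contig = genome[site.chrom]
    except KeyError:
        raise KeyError(f"chromosome {site.chrom!r} not in genome") from None
    start, stop = site.center - WINDOW_FLANK, site.center + WINDOW_FLANK + 1
    if stop > len(contig):
        raise IndexError(
            f"window [{start},{stop}) exceeds {site.chrom} length {len(contig)}"
        )
    seq = str(contig[start:stop]).upper().replace("T", "U")
    if site.strand == "-":
        seq = reverse_complement(seq)
        if region_labels is not None:
            region_labels = list(region_labels)[::-1]
        if cobind_counts is not None:
            cobind_counts = np.asarray(cobind_counts)[::-1]
        if structure_probs is not None:
            structure_probs = np.asarray(structure_probs)[::-1]
    return Window(
        sequence=seq,
        region_labels=list(region_labels) if region_labels is not None else [],
        cobind_counts=cobind_counts,
        structure_probs=structure_probs,
    )


def read_matrix(path: str | Path, dtype=None) -> np.ndarray:
    """Read a rectangular tab/comma-delimited numeric matrix (one sample per row).

    A header row of non-numeric tokens is skipped.  Integer input stays
    integer; ragged rows or NaN cells raise with the offending location.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else None
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         engine="python", skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed matrix: {exc}") from None
    # drop a header row if the first row failed numeric conversion
    if df.iloc[0].apply(lambda x: isinstance(x, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from None
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(f"{path}: NaN at row {r}, column {c}")
    if dtype is not None:
        return arr.astype(dtype)
    if np.allclose(arr, np.round(arr)):
        return arr.astype(np.int64)
    return arr


def write_matrix(arr: np.ndarray, path: str | Path) -> None:
    """Write a matrix as TSV, preserving integer formatting where exact."""
    arr = np.asarray(arr)
    fmt = "%d" if np.issubdtype(arr.dtype, np.integer) else "%.10g"
    np.savetxt(path, np.atleast_2d(arr), fmt=fmt, delimiter="\t")


def load_benchmark_dir(path: str | Path):
    """Optional loader for a pre-encoded benchmark directory.

    Expects ``matrix_RegionType.tsv``, ``matrix_Cobinding.tsv``,
    ``matrix_RNAfold.tsv``, ``matrix_Response.tsv`` and ``sequences.fa``
    inside ``path`` — the layout public CLIP feature releases use.  Returns
    a dict of arrays plus the sequence list.  No test depends on this; it
    exists so real benchmark downloads drop straight in.
    """
    path = Path(path)
    out: dict[str, np.ndarray] = {}
    names = {
        "region_type": "matrix_RegionType.tsv",
        "cobinding": "matrix_Cobinding.tsv",
        "structure": "matrix_RNAfold.tsv",
        "labels": "matrix_Response.tsv",
    }
    for key, fname in names.items():
        f = path / fname
        if f.exists():
            out[key] = read_matrix(f)
    fa = path / "sequences.fa"
    if fa.exists():
        from Bio import SeqIO

        out["sequences"] = [
            str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(fa), "fasta")
        ]
    return out
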