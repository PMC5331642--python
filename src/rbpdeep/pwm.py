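"""Position weight matrices and the MEME-minimal motif format.

A :class:`PWM` stores both the raw nucleotide counts and the
pseudocount-regularised probability matrix (rows A, C, G, U), so the
provenance of every probability column is recoverable.  The module also
houses :class:`PWMLibrary` (a named collection of PWMs plus a background
distribution) and readers/writers for the MEME-minimal text format and a
plain 4-row matrix format, the two layouts motif catalogues such as
CISBP-RNA commonly ship in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "PWM",
    "PWMLibrary",
    "pwm_from_counts",
    "pwm_from_probs",
    "read_meme",
    "write_meme",
    "read_matrix_library",
]


@dataclass
class PWM:
    """A motif as a 4 x w probability matrix with count provenance.

    Attributes
    ----------
    probs
        4 x w matrix, rows in A, C, G, U order; every column sums to 1.
    counts
        4 x w non-negative matrix of nucleotide tallies the probabilities
        were derived from (zeros when the PWM was specified directly as
        probabilities).
    n_sites
        Number of sequences tallied into ``counts``; 0 for a degenerate or
        directly-specified PWM.
    pseudocount
        Per-cell pseudocount added before column normalisation.
    id
        Motif identifier.
    """

    probs: np.ndarray
    counts: np.ndarray
    n_sites: int
    pseudocount: float
    id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError(f"PWM probs must have 4 rows, got {self.probs.shape}")
        if self.probs.shape != self.counts.shape:
            raise ValueError("probs and counts shapes differ")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("every PWM column must sum to 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        """Most probable base per column."""
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def log_odds(self, background: np.ndarray | None = None,
                 pseudocount: float = 1e-3) -> np.ndarray:
        """4 x w log2-odds matrix against ``background`` (uniform default).

        Probabilities are re-regularised with ``pseudocount`` so zero
        entries stay finite.
        """
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = (self.probs + pseudocount) / (1.0 + 4.0 * pseudocount)
        return np.log2(p / bg[:, None])


def pwm_from_counts(counts: np.ndarray, pseudocount: float = 1.0,
                    n_sites: int | None = None, id: str = "") -> PWM:
    """Build a PWM from a 4 x w count matrix by pseudocount normalisation."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x w matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    reg = counts + pseudocount
    probs = reg / reg.sum(axis=0, keepdims=True)
    if n_sites is None:
        n_sites = int(round(counts.sum(axis=0).max())) if counts.size else 0
    return PWM(probs=probs, counts=counts, n_sites=n_sites,
               pseudocount=pseudocount, id=id)


def pwm_from_probs(probs: np.ndarray, id: str = "", n_sites: int = 0) -> PWM:
    """Wrap an existing 4 x w probability matrix (no count provenance)."""
    probs = np.asarray(probs, dtype=float)
    return PWM(probs=probs, counts=np.zeros_like(probs), n_sites=n_sites,
               pseudocount=0.0, id=id)


@dataclass
class PWMLibrary:
    """A named set of PWMs with a shared background distribution."""

    pwms: list[PWM] = field(default_factory=list)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,):
            raise ValueError("background must be a length-4 vector")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return len(self.pwms)

    def __iter__(self):
        return iter(self.pwms)

    def __getitem__(self, i: int) -> PWM:
        return self.pwms[i]

    def ids(self) -> list[str]:
        return [p.id for p in self.pwms]


# ---------------------------------------------------------------------------
# MEME-minimal format
# ---------------------------------------------------------------------------

def write_meme(pwms: Sequence[PWM], path: str | Path,
               background: np.ndarray | None = None) -> None:
    """Write motifs as a MEME-minimal file (ACGU alphabet).

    The file round-trips through :func:`read_meme` preserving widths and
    probabilities to ~1e-4 (six printed decimals).
    """
    pwms = list(pwms)
    if not pwms:
        raise ValueError("cannot write an empty motif list")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lines = ["MEME version 4", "", "ALPHABET= ACGU", "", "strands: +", "",
             "Background letter frequencies",
             " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)), ""]
    for i, pwm in enumerate(pwms):
        name = pwm.id or f"motif_{i}"
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {max(pwm.n_sites, 1)} E= 0"
        )
        for col in pwm.probs.T:
            lines.append(" " + " ".join(f"{x:.6f}" for x in col))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> PWMLibrary:
    """Parse a MEME-minimal motif file into a :class:`PWMLibrary`."""
    text = Path(path).read_text()
    bg = np.full(4, 0.25)
    m = re.search(r"Background letter frequencies.*?\n([^\n]+)", text)
    if m:
        nums = re.findall(r"([\d.eE+-]+)", m.group(1))
        vals = [float(x) for x in nums if _is_float(x)]
        if len(vals) >= 4:
            bg = np.asarray(vals[:4])
            bg = bg / bg.sum()
    pwms: list[PWM] = []
    blocks = re.split(r"\nMOTIF\s+", "\n" + text)
    for block in blocks[1:]:
        header, *rest = block.splitlines()
        name = header.split()[0]
        body = "\n".join(rest)
        mw = re.search(r"letter-probability matrix:[^\n]*w=\s*(\d+)", body)
        if not mw:
            raise ValueError(f"motif {name}: missing letter-probability matrix")
        w = int(mw.group(1))
        ns = re.search(r"nsites=\s*(\d+)", body)
        n_sites = int(ns.group(1)) if ns else 0
        rows: list[list[float]] = []
        for line in body[mw.end():].splitlines():
            parts = line.split()
            if len(parts) == 4 and all(_is_float(p) for p in parts):
                rows.append([float(p) for p in parts])
                if len(rows) == w:
                    break
        if len(rows) != w:
            raise ValueError(f"motif {name}: expected {w} matrix rows, got {len(rows)}")
        probs = np.asarray(rows).T  # file is w x 4, we store 4 x w
        probs = probs / probs.sum(axis=0, keepdims=True)
        pwms.append(pwm_from_probs(probs, id=name, n_sites=n_sites))
    return PWMLibrary(pwms=pwms, background=bg)


def read_matrix_library(paths: Iterable[str | Path]) -> PWMLibrary:
    """Read plain 4-row matrix files (one motif per file, rows A,C,G,U).

    Accepts whitespace-delimited numbers, optionally with a leading base
    letter per row — the common plain-text layout of CISBP-RNA-style motif
    tables.
    """
    pwms = []
    for path in paths:
        path = Path(path)
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if parts and parts[0].upper() in ("A", "C", "G", "U", "T"):
                parts = parts[1:]
            if parts and all(_is_float(p) for p in parts):
                rows.append([float(p) for p in parts])
        if len(rows) != 4:
            raise ValueError(f"{path}: expected 4 numeric rows, got {len(rows)}")
        probs = np.asarray(rows)
        probs = probs / probs.sum(axis=0, keepdims=True)
        pwms.append(pwm_from_probs(probs, id=path.stem))
    return PWMLibrary(pwms=pwms)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
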