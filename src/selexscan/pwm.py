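"""Position weight matrices, IUPAC consensus patterns and MEME minimal motif I/O.

A motif here is a position-dependent letter-probability matrix: one probability
distribution over A/C/G/T per motif position.  Homodimeric CRP/FNR-family
regulators bind dyad (inverted-repeat) sites, so the module also provides the
palindromic block extension used to turn one half-site block of a discovered
matrix into a full, exactly self-reverse-complementary dyad matrix.

All user-facing matrix positions are 1-based, matching the convention used in
motif reports; internal arrays are 0-based numpy.
"""
from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np

from .seqs import DNA, revcomp

#: IUPAC degenerate nucleotide codes -> set of allowed bases.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items()}

#: Boolean (code -> allowed base indices) lookup in ACGT order.
IUPAC_MASKS: dict[str, np.ndarray] = {
    code: np.array([b in allowed for b in DNA], dtype=bool)
    for code, allowed in IUPAC_SETS.items()
}


@dataclasses.dataclass
class PWMotif:
    """A letter-probability matrix with background and site count.

    Parameters
    ----------
    matrix:
        Array of shape (width, 4) in ACGT order; each row is a probability
        distribution over bases at that motif position.
    background:
        0-order background base probabilities (ACGT order), default uniform.
    nsites:
        Number of sequences/sites that contributed to the matrix.
    score_significance:
        Log-likelihood-ratio statistic of the discovery run that produced the
        motif (a relative measure; this package does not compute MEME E-values).
    """

    matrix: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]
    nsites: int = 0
    score_significance: float | None = None
    name: str = "motif_1"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (width, 4)")
        if self.matrix.shape[0] < 1:
            raise ValueError("motif width must be >= 1")
        if (self.matrix < -1e-12).any():
            raise ValueError("matrix probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each matrix position must sum to 1 (within 1e-6)")
        # Renormalise only when needed: exact inputs (e.g. palindromised
        # matrices, where mirror-symmetry must hold bitwise) pass through
        # untouched, while file-parsed matrices get cleaned up.
        if (self.matrix < 0).any() or not np.allclose(sums, 1.0, atol=1e-12):
            self.matrix = np.clip(self.matrix, 0.0, None)
            self.matrix = self.matrix / self.matrix.sum(axis=1, keepdims=True)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def column(self, i: int) -> np.ndarray:
        """Probability distribution at 1-based motif position ``i``."""
        if not 1 <= i <= self.width:
            raise IndexError(f"position {i} outside 1..{self.width}")
        return self.matrix[i - 1]

    def reverse_complement(self) -> "PWMotif":
        return dataclasses.replace(self, matrix=self.matrix[::-1, ::-1].copy())

    def log_odds(self, background: np.ndarray | None = None, pseudocount: float = 0.0) -> np.ndarray:
        """Log2-odds score matrix: ``log2((p + pc) / bg)`` per cell."""
        bg = self.background if background is None else np.asarray(background, dtype=float)
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix + pseudocount) - np.log2(bg)[None, :]

    def max_score_word(self) -> str:
        """Concatenation of the per-position most probable bases."""
        return "".join(DNA[i] for i in self.matrix.argmax(axis=1))


@dataclasses.dataclass(frozen=True)
class ConsensusPattern:
    """IUPAC consensus with inferred dyad (half-site/spacer) structure."""

    iupac: str
    half_site_length: int
    spacer_length: int

    def __post_init__(self) -> None:
        bad = [c for c in self.iupac if c not in IUPAC_SETS]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad!r}")
        if 2 * self.half_site_length + self.spacer_length != len(self.iupac):
            raise ValueError("2*half_site_length + spacer_length must equal pattern length")

    @classmethod
    def from_iupac(cls, iupac: str) -> "ConsensusPattern":
        """Infer dyad structure from the central maximal all-N run.

        If an interior run of N splits the pattern into equal-length N-free
        half sites, those are the dyad half sites and the run is the spacer;
        otherwise the pattern is treated as non-dyadic (half_site_length 0).
        """
        runs = [(m.start(), m.end()) for m in re.finditer(r"N+", iupac)]
        interior = [(s, e) for s, e in runs if s > 0 and e < len(iupac)]
        if interior:
            s, e = max(interior, key=lambda r: r[1] - r[0])
            left, right = iupac[:s], iupac[e:]
            if len(left) == len(right) and "N" not in left and "N" not in right:
                return cls(iupac, half_site_length=len(left), spacer_length=e - s)
        return cls(iupac, half_site_length=0, spacer_length=len(iupac))

    @property
    def half_sites(self) -> tuple[str, str]:
        h = self.half_site_length
        return self.iupac[:h], self.iupac[len(self.iupac) - h:]

    def __str__(self) -> str:
        return self.iupac


def iupac_mismatches(seq: str, pattern: str) -> int:
    """Number of positions where ``seq``'s base falls outside the IUPAC code's set.

    ``N`` in the pattern allows any base; the comparison is case-insensitive.
    """
    seq = seq.upper()
    pattern = pattern.upper()
    if len(seq) != len(pattern):
        raise ValueError(f"sequence length {len(seq)} != pattern length {len(pattern)}")
    n = 0
    for base, code in zip(seq, pattern):
        try:
            allowed = IUPAC_SETS[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern") from None
        if base not in allowed:
            if base not in DNA:
                raise ValueError(f"invalid base {base!r} in sequence")
            n += 1
    return n


def spacer_variants(pattern: ConsensusPattern, delta: int) -> ConsensusPattern:
    """Same half sites with the spacer lengthened (+delta) or shortened (-delta)."""
    if pattern.half_site_length == 0:
        raise ValueError("pattern has no dyad structure; cannot vary the spacer")
    new_spacer = pattern.spacer_length + delta
    if new_spacer < 0:
        raise ValueError(f"resulting spacer length {new_spacer} is negative")
    left, right = pattern.half_sites
    return ConsensusPattern(
        left + "N" * new_spacer + right,
        half_site_length=pattern.half_site_length,
        spacer_length=new_spacer,
    )


def extend_palindromic(
    pwm: PWMotif, block_start: int, block_end: int, mode: str = "mirror"
) -> PWMotif:
    """Extend a matrix block into an exactly self-reverse-complementary dyad matrix.

    With B = positions ``block_start..block_end`` (1-based, inclusive; L
    columns), the output is B followed by the reverse complement of B (width
    2L).  ``mode="average"`` first symmetrises B with its own reverse
    complement before mirroring; the default concatenation-with-mirror is the
    construction consistent with extending an 11-position half-site block into
    a 22-position dyad matrix.
    """
    if not 1 <= block_start <= block_end <= pwm.width:
        raise ValueError(
            f"invalid block bounds {block_start}..{block_end} for width {pwm.width}"
        )
    block = pwm.matrix[block_start - 1 : block_end].copy()
    if mode == "average":
        block = 0.5 * (block + block[::-1, ::-1])
    elif mode != "mirror":
        raise ValueError(f"unknown mode {mode!r}")
    extended = np.vstack([block, block[::-1, ::-1]])
    return PWMotif(
        matrix=extended,
        background=pwm.background.copy(),
        nsites=pwm.nsites,
        score_significance=pwm.score_significance,
        name=f"{pwm.name}_ext",
    )


class MemeParseError(ValueError):
    """Raised for malformed MEME minimal motif files; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


def write_meme_minimal(pwm: PWMotif, path: str | Path) -> None:
    """Write a motif in MEME minimal format (version, alphabet, strands, matrix)."""
    bg = pwm.background
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.6f}" for b, p in zip(DNA, bg)),
        "",
        f"MOTIF {pwm.name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {max(pwm.nsites, 1)} E= 0",
    ]
    for row in pwm.matrix:
        lines.append(" " + " ".join(f"{p:.6f}" for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme_minimal(path: str | Path) -> PWMotif:
    """Parse a MEME minimal motif file (first motif block)."""
    text = Path(path).read_text().splitlines()
    version_seen = alphabet_seen = False
    background = np.full(4, 0.25)
    name = "motif_1"
    i = 0
    matrix_rows: list[list[float]] = []
    width = nsites = None
    while i < len(text):
        line = text[i].strip()
        if line.startswith("MEME version"):
            version_seen = True
        elif line.startswith("ALPHABET"):
            alphabet_seen = True
            alpha = line.split("=", 1)[-1].strip()
            if alpha.upper() != "ACGT":
                raise MemeParseError(f"unsupported alphabet {alpha!r}", i + 1)
        elif line.startswith("Background letter frequencies"):
            i += 1
            if i >= len(text):
                raise MemeParseError("missing background frequency values", i)
            toks = text[i].split()
            try:
                freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
                background = np.array([freq[b] for b in DNA])
            except (IndexError, KeyError, ValueError):
                raise MemeParseError("malformed background frequency line", i + 1) from None
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) > 1:
                name = parts[1]
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            if m is None:
                raise MemeParseError("matrix header missing 'w=' width", i + 1)
            width = int(m.group(1))
            m = re.search(r"nsites=\s*(\d+)", line)
            nsites = int(m.group(1)) if m else 0
            for j in range(width):
                i += 1
                if i >= len(text):
                    raise MemeParseError(f"matrix truncated: expected {width} rows", i)
                toks = text[i].split()
                if len(toks) != 4:
                    raise MemeParseError(
                        f"matrix row has {len(toks)} fields, expected 4", i + 1
                    )
                try:
                    matrix_rows.append([float(t) for t in toks])
                except ValueError:
                    raise MemeParseError("non-numeric matrix entry", i + 1) from None
            break
        i += 1
    if not version_seen:
        raise MemeParseError("missing 'MEME version' section")
    if not alphabet_seen:
        raise MemeParseError("missing 'ALPHABET' section")
    if width is None:
        raise MemeParseError("missing 'letter-probability matrix' section")
    return PWMotif(
        matrix=np.array(matrix_rows),
        background=background,
        nsites=int(nsites or 0),
        name=name,
    )


def pattern_revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern string."""
    return revcomp(pattern)
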