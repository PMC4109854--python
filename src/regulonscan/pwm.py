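"""Position weight matrices and the count-matrix dialects they travel in.

A :class:`PWM` stores a named nucleotide *count* matrix (positions x ACGT).
Counts are kept as provided (typically scaled to 100 when the source is a
frequency matrix); probabilities are derived on demand with an additive
pseudocount per cell.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Additive count per matrix cell when converting counts to probabilities.
DEFAULT_PSEUDOCOUNT = 0.375

#: Minimum motif width accepted by scoring and similarity operations.
MIN_SCORING_WIDTH = 4


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (A<->T, C<->G, N fixed)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A named nucleotide count matrix in A,C,G,T column order."""

    motif_id: str
    counts: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: counts must be (positions, 4)")
        if counts.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: empty matrix")
        if np.any(counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError(f"{self.motif_id}: position with all-zero counts")
        self.counts = counts

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def probabilities(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """Per-position base probabilities with an additive pseudocount."""
        p = self.counts + pseudocount
        return p / p.sum(axis=1, keepdims=True)

    def log_odds(
        self,
        background: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> np.ndarray:
        """Per-position log2(p_motif / p_background) over A,C,G,T."""
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
        return np.log2(self.probabilities(pseudocount)) - np.log2(bg)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.counts[::-1, ::-1].copy(), self.source_tag)

    def column_shuffled(self, rng: np.random.Generator) -> "PWM":
        """A decoy with the same columns in seeded-random order."""
        perm = rng.permutation(self.width)
        return PWM(self.motif_id + "_shuf", self.counts[perm].copy(), self.source_tag)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def information_content(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
        """Total information content in bits against a uniform background."""
        p = self.probabilities(pseudocount)
        return float((p * np.log2(p * 4.0)).sum())


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def parse_clusterbuster(text: str, source_tag: str = "clusterbuster") -> list[PWM]:
    """Parse ``>id`` headers followed by rows of four counts (A C G T)."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is not None:
            pwms.append(PWM(name, np.array(rows, dtype=float), source_tag))

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            rows = []
        else:
            vals = line.split()
            if len(vals) != 4:
                raise ValueError(f"expected 4 counts per row, got: {line!r}")
            rows.append([float(v) for v in vals])
    flush()
    return pwms


_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[([^\]]*)\]")


def parse_jaspar(text: str, source_tag: str = "jaspar") -> list[PWM]:
    """Parse JASPAR matrices: ``>ID name`` then ``A [ 1 2 ... ]`` rows."""
    pwms: list[PWM] = []
    name = None
    per_base: dict[str, list[float]] = {}

    def flush() -> None:
        if name is None:
            return
        missing = [b for b in BASES if b not in per_base]
        if missing:
            raise ValueError(f"{name}: missing rows for {missing}")
        mat = np.array([per_base[b] for b in BASES], dtype=float).T
        pwms.append(PWM(name, mat, source_tag))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            per_base = {}
            continue
        m = _JASPAR_ROW.match(line)
        if m:
            per_base[m.group(1)] = [float(v) for v in m.group(2).split()]
        else:
            # bare 4-row variant without base labels / brackets
            vals = line.split()
            base = "ACGT"[len(per_base)]
            per_base[base] = [float(v) for v in vals]
    flush()
    return pwms


def parse_transfac(text: str, source_tag: str = "transfac") -> list[PWM]:
    """Parse TRANSFAC-like blocks: ``ID``/``DE`` header, ``P0`` column header,
    numbered rows of four counts (+ optional consensus letter), ``//`` ends."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal name, rows, in_matrix
        if name is not None and rows:
            pwms.append(PWM(name, np.array(rows, dtype=float), source_tag))
        name, rows, in_matrix = None, [], False

    for raw in text.splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("//"):
            flush()
        elif line.startswith(("ID", "AC")) and name is None:
            name = line.split(maxsplit=1)[1].strip()
        elif line.startswith("DE") and name is None:
            name = line.split(maxsplit=1)[1].strip()
        elif line.startswith("P0") or line.startswith("PO"):
            in_matrix = True
        elif in_matrix and line[:2].strip().isdigit():
            vals = line.split()
            rows.append([float(v) for v in vals[1:5]])
    flush()
    return pwms


def write_clusterbuster(pwms: list[PWM]) -> str:
    """Serialize PWMs in the internal (Cluster-Buster style) dialect."""
    out = io.StringIO()
    for pwm in pwms:
        out.write(f">{pwm.motif_id}\n")
        for row in pwm.counts:
            out.write("\t".join(f"{v:g}" for v in row) + "\n")
    return out.getvalue()


def read_pwm_file(path: str, dialect: str = "clusterbuster") -> list[PWM]:
    with open(path) as fh:
        text = fh.read()
    parser = {
        "clusterbuster": parse_clusterbuster,
        "jaspar": parse_jaspar,
        "transfac": parse_transfac,
    }.get(dialect)
    if parser is None:
        raise ValueError(f"unknown PWM dialect: {dialect}")
    return parser(text)
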