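"""Readers and writers for trees, alignments, calibrations and fossil ages.

File formats
------------
* trees: Newick with branch lengths as durations in Myr (dendropy backend);
* alignments: FASTA or relaxed PHYLIP (Biopython backend);
* calibrations: tab-separated ``cladeName<TAB>tip1,tip2<TAB>lo<TAB>hi`` with
  empty fields meaning "unbounded";
* fossil age intervals: tab-separated ``tipLabel<TAB>minAge<TAB>maxAge``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .timetree import TimeTree

__all__ = [
    "Alignment", "CalibrationSet", "Calibration", "read_newick", "write_newick",
    "read_alignment", "read_calibrations", "resolve_calibrations",
    "read_fossil_intervals",
]

# IUPAC nucleotide codes as bitmasks over (A, C, G, T)
_CODE = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001, "K": 0b1100,
    "M": 0b0011, "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111, "X": 0b1111, "O": 0b1111,
}
_BASES = "ACGT"


@dataclass
class Alignment:
    """Nucleotide alignment stored as IUPAC bitmasks over (A,C,G,T).

    ``codes[i, s]`` is a 4-bit mask of the states compatible with taxon *i*
    at site *s* (ambiguity codes are unions; gaps are fully missing).
    """

    labels: list[str]
    codes: np.ndarray  # (n_taxa, n_sites) uint8 bitmasks

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if len(self.labels) != self.codes.shape[0]:
            raise ValueError("label count does not match sequence count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels in alignment")
        if np.any(self.codes == 0) or np.any(self.codes > 15):
            raise ValueError("invalid state code in alignment")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def masks(self) -> np.ndarray:
        """(n_taxa, n_sites, 4) float partial-likelihood masks."""
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        return ((self.codes[:, :, None] & bits[None, None, :]) > 0).astype(float)

    def sequences(self) -> list[str]:
        inv = {v: k for k, v in _CODE.items() if k not in "U?XO-"}
        inv[15] = "N"
        return ["".join(inv[c] for c in row) for row in self.codes]

    @classmethod
    def from_strings(cls, labels, seqs) -> "Alignment":
        seqs = [s.upper() for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        n_sites = lengths.pop()
        codes = np.zeros((len(seqs), n_sites), dtype=np.uint8)
        for i, s in enumerate(seqs):
            for j, ch in enumerate(s):
                try:
                    codes[i, j] = _CODE[ch]
                except KeyError:
                    raise ValueError(
                        f"unknown symbol {ch!r} in sequence {labels[i]!r}") from None
        return cls(list(labels), codes)

    @classmethod
    def from_states(cls, labels, states: np.ndarray) -> "Alignment":
        """Build from an integer state matrix (0=A,1=C,2=G,3=T)."""
        return cls(list(labels), np.left_shift(1, np.asarray(states)).astype(np.uint8))

    def check_against_tree(self, tree: TimeTree) -> None:
        tree_labels = set(tree.labels.values())
        aln_labels = set(self.labels)
        if aln_labels != tree_labels:
            missing = sorted(tree_labels - aln_labels)
            extra = sorted(aln_labels - tree_labels)
            raise ValueError(
                f"alignment/tree taxon mismatch; missing from alignment: {missing}; "
                f"not in tree: {extra}")


def read_newick(source, fossil_tips=None) -> TimeTree:
    """Read a rooted binary Newick tree with durations in Myr.

    ``source`` is a path or a Newick string.  Tips listed in ``fossil_tips``
    are allowed to end above the present; all remaining tips must be
    contemporaneous (age 0), otherwise the tree is rejected as
    non-ultrametric.
    """
    text = source
    p = Path(str(source))
    if "(" not in str(source) and p.exists():
        text = p.read_text()
    return TimeTree.from_newick(text, fossil_tips=fossil_tips)


def write_newick(tree: TimeTree, path=None) -> str:
    s = tree.to_newick()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def read_alignment(source, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment."""
    if format not in ("fasta", "phylip"):
        raise ValueError(f"unsupported alignment format {format!r}")
    schema = "fasta" if format == "fasta" else "phylip-relaxed"
    msa = AlignIO.read(str(source), schema)
    return Alignment.from_strings([rec.id for rec in msa],
                                  [str(rec.seq) for rec in msa])


@dataclass
class Calibration:
    name: str
    tips: tuple[str, ...]
    lo: float | None
    hi: float | None

    def __post_init__(self):
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise ValueError(
                f"calibration {self.name!r}: lower bound {self.lo} must be "
                f"< upper bound {self.hi}")


@dataclass
class CalibrationSet:
    calibrations: list[Calibration]

    def __iter__(self):
        return iter(self.calibrations)

    def __len__(self):
        return len(self.calibrations)


def read_calibrations(source) -> CalibrationSet:
    out = []
    for ln, line in enumerate(Path(source).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"calibration file line {ln}: expected 4 tab-separated "
                             f"fields, got {len(parts)}")
        name, tips, lo, hi = parts
        out.append(Calibration(name, tuple(t.strip() for t in tips.split(",")),
                               float(lo) if lo.strip() else None,
                               float(hi) if hi.strip() else None))
    return CalibrationSet(out)


def resolve_calibrations(tree: TimeTree, cal: CalibrationSet,
                         strict: bool = False) -> dict[int, tuple]:
    """Map each calibrated clade to its MRCA node.

    Returns ``{node: (lo, hi)}`` with ``None`` for absent bounds.  Listed tips
    are representatives: the bound attaches to their MRCA.  With
    ``strict=True`` the listed tips must be the complete, monophyletic tip
    set of that node, and intruding taxa are reported.
    """
    bounds: dict[int, tuple] = {}
    for c in cal:
        node = tree.mrca(c.tips) if len(c.tips) > 1 else tree.tip_label_to_node[c.tips[0]]
        clade = tree.tipset_below(node)
        if strict and clade != set(c.tips):
            raise ValueError(
                f"calibration {c.name!r} is not monophyletic: MRCA also contains "
                f"{sorted(clade - set(c.tips))}")
        lo, hi = bounds.get(node, (None, None))
        lo = c.lo if lo is None else (lo if c.lo is None else max(lo, c.lo))
        hi = c.hi if hi is None else (hi if c.hi is None else min(hi, c.hi))
        if lo is not None and hi is not None and not lo < hi:
            raise ValueError(f"conflicting bounds on node of {c.name!r}: ({lo}, {hi})")
        bounds[node] = (lo, hi)
    return bounds


def read_fossil_intervals(source) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for ln, line in enumerate(Path(source).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"fossil interval file line {ln}: expected 3 fields")
        lab, lo, hi = parts[0], float(parts[1]), float(parts[2])
        if not 0 < lo <= hi:
            raise ValueError(f"fossil {lab!r}: need 0 < min <= max, got ({lo}, {hi})")
        out[lab] = (lo, hi)
    return out
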