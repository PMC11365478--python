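"""Binary cis/trans regulatory regions and the gene-interaction matrix.

Each gene carries two binary regulatory regions of identical length ``L``:

* a *cis* region, the stretch upstream of the gene on which the trans
  regions of other genes bind, and
* a *trans* region, through which the gene regulates other genes' cis
  regions.

Positions ``1..L-1`` of a region (1-based, as written in the format docs)
are *strength bits*; position ``L`` is the *type bit*.  Internally regions
are stored 0-based in ``numpy`` ``uint8`` arrays, so strength bits occupy
indices ``0..L-2`` and the type bit index ``L-1``.

The signed interaction of trans region ``j`` on cis region ``i`` is

    |I| = popcount(cis_strength & trans_strength) / L

gated and signed by the two type bits: a cis type bit of 0 accepts no
regulation at all (interaction 0); otherwise the trans type bit selects
activation (+) or repression (-).  All interactions of an individual are
collected in the n-by-n matrix ``M`` whose entry ``(i, j)`` is the effect
of gene ``j``'s trans region on gene ``i``'s cis region, so row ``i``
gathers everything that regulates gene ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "Genome",
    "interaction",
    "build_interaction_matrix",
    "refresh_after_mutation",
    "write_genome",
    "read_genome",
    "write_edge_list",
]


@dataclass
class Genome:
    """Heritable unit: ``n`` genes, each with one cis and one trans region.

    ``cis`` and ``trans`` are ``(n, L)`` uint8 arrays of 0/1 values.
    Instances are treated as immutable by the simulation engine; any
    operator that changes bits copies first.
    """

    cis: np.ndarray
    trans: np.ndarray

    def __post_init__(self) -> None:
        self.cis = np.ascontiguousarray(self.cis, dtype=np.uint8)
        self.trans = np.ascontiguousarray(self.trans, dtype=np.uint8)
        if self.cis.ndim != 2 or self.cis.shape != self.trans.shape:
            raise ValueError("cis and trans must be (n, L) arrays of equal shape")
        n, L = self.cis.shape
        if n < 1:
            raise ValueError("a genome needs at least one gene")
        if L < 2:
            raise ValueError("region length L must be at least 2")
        for arr in (self.cis, self.trans):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("regulatory regions must be binary")

    @property
    def n(self) -> int:
        return self.cis.shape[0]

    @property
    def L(self) -> int:
        return self.cis.shape[1]

    def copy(self) -> "Genome":
        return Genome(self.cis.copy(), self.trans.copy())

    def key(self) -> bytes:
        """Compact hashable identity of the full 2nL-bit genome."""
        return np.packbits(np.concatenate([self.cis.ravel(), self.trans.ravel()])).tobytes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return np.array_equal(self.cis, other.cis) and np.array_equal(self.trans, other.trans)


def _check_region(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region, dtype=np.uint8)
    if region.ndim != 1 or region.size < 2:
        raise ValueError("a regulatory region is a 1-D binary vector of length >= 2")
    return region


def interaction(cis: np.ndarray, trans: np.ndarray) -> float:
    """Signed interaction strength of a trans region on a cis region.

    Returns 0 when the cis type bit is 0 (the gene accepts no regulation).
    Otherwise the magnitude is the number of strength-bit positions where
    both regions carry a 1, divided by ``L``; the sign follows the trans
    type bit (1 -> activation, 0 -> repression).
    """
    cis = _check_region(cis)
    trans = _check_region(trans)
    if cis.size != trans.size:
        raise ValueError(f"region lengths differ: {cis.size} != {trans.size}")
    L = cis.size
    if cis[-1] == 0:
        return 0.0
    shared = int(np.count_nonzero(cis[:-1] & trans[:-1]))
    if shared == 0:
        return 0.0
    magnitude = shared / L
    return magnitude if trans[-1] == 1 else -magnitude


def build_interaction_matrix(genome: Genome) -> np.ndarray:
    """Full n-by-n interaction matrix of a genome, entry (i, j) =
    interaction(genes[i].cis, genes[j].trans); the diagonal (self-regulation)
    is computed by the same rule."""
    L = genome.L
    cis_s = genome.cis[:, :-1].astype(np.int64)
    trans_s = genome.trans[:, :-1].astype(np.int64)
    shared = cis_s @ trans_s.T  # (i, j): common set strength bits
    accepts = genome.cis[:, -1].astype(np.float64)[:, None]
    tsign = np.where(genome.trans[:, -1] == 1, 1.0, -1.0)[None, :]
    # "+ 0.0" normalises -0.0 entries produced by the sign factor
    return accepts * (shared / L) * tsign + 0.0


def refresh_after_mutation(
    matrix: np.ndarray, genome: Genome, gene_index: int, region_kind: str
) -> np.ndarray:
    """Incrementally update ``matrix`` after one region of one gene changed.

    A cis change can only alter how gene ``gene_index`` is regulated, i.e.
    row ``gene_index``; a trans change can only alter how it regulates
    others, i.e. column ``gene_index``.  The matrix is updated in place and
    returned.
    """
    n, L = genome.n, genome.L
    if not 0 <= gene_index < n:
        raise IndexError(f"gene index {gene_index} out of range for n={n}")
    trans_s = genome.trans[:, :-1].astype(np.int64)
    tsign = np.where(genome.trans[:, -1] == 1, 1.0, -1.0)
    if region_kind == "cis":
        cis = genome.cis[gene_index]
        if cis[-1] == 0:
            matrix[gene_index, :] = 0.0
        else:
            shared = trans_s @ cis[:-1].astype(np.int64)
            matrix[gene_index, :] = (shared / L) * tsign + 0.0
    elif region_kind == "trans":
        trans = genome.trans[gene_index]
        shared = genome.cis[:, :-1].astype(np.int64) @ trans[:-1].astype(np.int64)
        accepts = genome.cis[:, -1].astype(np.float64)
        sign = 1.0 if trans[-1] == 1 else -1.0
        matrix[:, gene_index] = accepts * (shared / L) * sign + 0.0
    else:
        raise ValueError("region_kind must be 'cis' or 'trans'")
    return matrix


# ---------------------------------------------------------------------------
# Plain-text serialization

def _bits_to_str(bits: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in bits)


def write_genome(genome: Genome, path: Union[str, Path]) -> None:
    """One gene per line: ``index<TAB>cis_bits<TAB>trans_bits`` (position 1
    leftmost, type bit rightmost), preceded by a ``#genes=n L=...`` header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#genes={genome.n} L={genome.L}\n")
        for i in range(genome.n):
            fh.write(f"{i}\t{_bits_to_str(genome.cis[i])}\t{_bits_to_str(genome.trans[i])}\n")


def read_genome(path: Union[str, Path]) -> Genome:
    cis_rows: list[list[int]] = []
    trans_rows: list[list[int]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, cis_str, trans_str = line.split("\t")
            cis_rows.append([int(c) for c in cis_str])
            trans_rows.append([int(c) for c in trans_str])
    return Genome(np.array(cis_rows, dtype=np.uint8), np.array(trans_rows, dtype=np.uint8))


def write_edge_list(matrix: np.ndarray, path: Union[str, Path]) -> None:
    """TSV edge list ``source<TAB>target<TAB>weight`` of nonzero interactions
    (source = regulator j, target = regulated gene i)."""
    matrix = np.asarray(matrix)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_gene\ttarget_gene\tweight\n")
        for i, j in zip(*np.nonzero(matrix)):
            fh.write(f"{j}\t{i}\t{matrix[i, j]:.10g}\n")
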