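"""Pairwise identity matrices and neighbor-joining trees for protein sets.

Every pair of sequences is globally aligned (Needleman–Wunsch with affine gap
penalties; BLOSUM62, gap open 10, gap extend 0.5 by default, via Biopython's
PairwiseAligner). Percent identity is the number of identical columns over
all alignment columns, gaps included, with terminal-gap columns excluded from
the count. Identities feed a distance matrix d = 1 − id/100, from which an
unrooted tree is built by the Saitou–Nei neighbor-joining agglomeration:
consistent (exact recovery of topology and branch lengths) whenever the input
distances are additive. Determinism contracts: joins tie-break on the lowest
index pair, and a negative NJ branch length is clamped to zero with the
deficit moved to its sister branch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .signature import SEQUENCE_ALPHABET

__all__ = [
    "AlignmentResult",
    "make_aligner",
    "align_global",
    "identity_matrix",
    "nj_tree",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with its score and percent identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences must have equal length")


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    """Global affine-gap aligner; a gap of length L costs open + (L−1)·extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical columns / total columns (gaps included, terminal gaps excluded)."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    # terminal gap runs in either sequence delimit the scored region
    def first_res(s: str) -> int:
        return len(s) - len(s.lstrip("-"))

    def last_res(s: str) -> int:
        return len(s.rstrip("-")) - 1

    start = max(first_res(aligned_a), first_res(aligned_b))
    end = min(last_res(aligned_a), last_res(aligned_b))
    if end < start:
        return 0.0
    n_cols = end - start + 1
    n_ident = sum(
        1
        for x, y in zip(aligned_a[start : end + 1], aligned_b[start : end + 1])
        if x == y and x != "-"
    )
    return 100.0 * n_ident / n_cols


def _validate_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence {name!r}")
    up = seq.upper()
    bad = set(up) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"illegal residues {sorted(bad)} in sequence {name!r}")
    return up


def align_global(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Ties between co-optimal alignments are broken deterministically by taking
    the aligner's first enumerated alignment.
    """
    a = _validate_protein(a, "a")
    b = _validate_protein(b, "b")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity_percent=percent_identity(ga, gb),
    )


def identity_matrix(
    sequences: dict[str, str],
    aligner: Align.PairwiseAligner | None = None,
    reference: str | None = None,
) -> tuple[pd.DataFrame, DistanceMatrix, dict | None]:
    """All-vs-all percent identities and the derived distance matrix.

    Returns the symmetric identity matrix (diagonal 100) as a DataFrame, the
    distance matrix d = 1 − id/100, and — when ``reference`` names one of the
    sequences — the min/max off-diagonal identity of that reference row,
    mirroring range statements like "shares 41 to 78% identity".
    """
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if reference is not None and reference not in sequences:
        raise ValueError(f"reference {reference!r} not in the sequence set")
    if aligner is None:
        aligner = make_aligner()
    n = len(labels)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            r = align_global(sequences[labels[i]], sequences[labels[j]], aligner)
            ident[i, j] = ident[j, i] = r.identity_percent
    id_df = pd.DataFrame(ident, index=labels, columns=labels)
    dm = DistanceMatrix(1.0 - ident / 100.0, ids=labels)
    ref_summary = None
    if reference is not None:
        row = id_df.loc[reference].drop(reference)
        ref_summary = {
            "reference": reference,
            "min_identity": float(row.min()),
            "max_identity": float(row.max()),
        }
    return id_df, dm, ref_summary


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; unrooted tree as a trifurcating root.

    Exact on additive distance matrices. Joins minimize the Q criterion with
    ties broken by the lowest (i, j) label-index pair; negative branch lengths
    are clamped to 0 with the deficit added to the sister branch.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN entries")
    nodes: list[TreeNode] = [TreeNode(name=lb) for lb in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin on the flattened row-major matrix
        flat = np.argmin(Q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            lj += li  # deficit moved to sister
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ai, aj = active[i], active[j]
        parent = TreeNode()
        ci, cj = nodes[ai], nodes[aj]
        ci.length, cj.length = float(li), float(lj)
        parent.append(ci)
        parent.append(cj)
        # distances from the new node to every remaining taxon
        new_row = 0.5 * (D[ai, :] + D[aj, :] - d_ij)
        D = np.vstack([D, new_row])
        D = np.column_stack([D, np.append(new_row, 0.0)])
        nodes.append(parent)
        new_idx = len(nodes) - 1
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    # resolve the final three nodes around an unrooted (trifurcating) center
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        child = nodes[idx]
        child.length = float(max(ln, 0.0))
        root.append(child)
    return root


_NEWICK_META = set("()[]{}:;,'\" \t\n")


def _format_label(label: str | None) -> str:
    if not label:
        return ""
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick; labels with metacharacters are quoted."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            body = _format_label(node.name)
        else:
            body = (
                "(" + ",".join(render(c) for c in node.children) + ")"
                + _format_label(node.name)
            )
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return render(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (single-quoted labels preserved verbatim)."""
    return TreeNode.read(io.StringIO(text), convert_underscores=False)
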