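"""Synthetic inputs with known ground truth for every pipeline stage.

Four generator families, all pure functions of their spec (seed included):

* signature-conformant protein sequences and evolved families, emulating the
  plant GIP set whose members share 41–78% identity with the reference;
* non-conformant decoys (single broken constraint, or shuffles) as negative
  controls for classifier specificity;
* far-UV CD spectra as noisy non-negative mixtures of basis curves;
* 2-D point patterns — CSR (Poisson), hard-core (regular, wild-type-like
  pore spacing) and Thomas cluster (mutant-like aggregation) — in a
  rectangular window.

Sequence evolution is deliberately minimal: Poisson substitutions per site
with uniform replacement over the other 19 residues and no indels, since only
percent identities (not model-based distances) are consumed downstream. With
``preserve_signature`` the constrained motif positions mutate only within
their allowed residue class, so every descendant still matches the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .cd_unmix import BasisSet, CDSpectrum
from .npc import PointPattern
from .signature import (
    AMINO_ACIDS,
    SignaturePattern,
    load_gip_signature,
    scan_sequence,
)

__all__ = [
    "FamilySpec",
    "PointProcessSpec",
    "SpectrumSpec",
    "star_tree",
    "gen_signature_sequence",
    "evolve_family",
    "gen_decoys",
    "gen_cd_spectrum",
    "gen_point_pattern",
]

_AA = sorted(AMINO_ACIDS)  # fixed order for reproducible draws
NM2_PER_UM2 = 1.0e6


def _uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class FamilySpec:
    """Parameters of a simulated protein family.

    ``substitution_rate`` is the expected substitutions per site per unit of
    branch length; ``tree`` is any skbio TreeNode with branch lengths (use
    :func:`star_tree` for a star topology). ``background_frequencies`` orders
    the 20 residues alphabetically and defaults to uniform 1/20.
    """

    root_length: int = 70
    substitution_rate: float = 0.1
    tree: TreeNode | None = None
    n_leaves: int = 10
    preserve_signature: bool = True
    pattern: SignaturePattern | None = None
    background_frequencies: np.ndarray = field(default_factory=_uniform_background)
    seed: int = 0

    def __post_init__(self):
        if self.substitution_rate < 0:
            raise ValueError("substitution rate must be >= 0")
        bg = np.asarray(self.background_frequencies, dtype=float)
        if bg.shape != (20,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError(
                "background frequencies must be a 20-vector of non-negative"
                " values summing to 1"
            )
        self.background_frequencies = bg


@dataclass
class PointProcessSpec:
    """A planar point process in a rectangular window (sides in nm).

    ``process`` is one of "csr", "hard-core", "thomas"; ``intensity`` is the
    target point density in points per μm². Hard-core patterns are drawn by
    dart throwing with a bounded number of attempts; Thomas patterns place
    CSR parents at ``parent_intensity`` per μm², each with Poisson
    ``mean_offspring`` children at isotropic Gaussian offsets of SD
    ``offspring_sd`` nm, clipped to the window.
    """

    window: tuple[float, float] = (1414.0, 1414.0)  # ~2 um^2
    process: str = "csr"
    intensity: float = 50.0
    hard_core_distance: float = 0.0
    parent_intensity: float | None = None  # Thomas; default intensity/μ
    mean_offspring: float = 10.0
    offspring_sd: float = 30.0
    seed: int = 0

    def __post_init__(self):
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError("window area must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.hard_core_distance < 0:
            raise ValueError("hard-core distance must be >= 0")
        if self.process not in {"csr", "hard-core", "thomas"}:
            raise ValueError(f"unknown process {self.process!r}")

    @property
    def area_um2(self) -> float:
        return self.window[0] * self.window[1] / NM2_PER_UM2


@dataclass
class SpectrumSpec:
    """A noisy non-negative mixture of basis CD curves on a wavelength grid.

    The default grid is 182–260 nm at 1 nm steps, the far-UV range of the
    measured spectra this generator stands in for. ``noise_sd`` is the per-
    wavelength additive Gaussian SD in mean-residue-ellipticity units.
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(182.0, 261.0, 1.0)
    )
    fractions: np.ndarray = field(default_factory=lambda: np.array([0.8, 0.1, 0.1]))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or len(wl) < 2 or not (np.diff(wl) > 0).all():
            raise ValueError("wavelength grid must be strictly increasing")
        f = np.asarray(self.fractions, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        self.wavelengths = wl
        self.fractions = f


def star_tree(n_leaves: int, depth: float = 1.0) -> TreeNode:
    """Star topology: ``n_leaves`` tips hanging off one root at ``depth``."""
    if n_leaves < 2:
        raise ValueError("a star tree needs at least 2 leaves")
    root = TreeNode()
    for i in range(n_leaves):
        root.append(TreeNode(name=f"t{i + 1}", length=depth))
    return root


def _draw_background(rng: np.random.Generator, n: int, bg: np.ndarray) -> list[str]:
    return list(rng.choice(_AA, size=n, p=bg))


def gen_signature_sequence(
    pattern: SignaturePattern,
    flank_lengths: tuple[int, int] = (0, 0),
    background: Sequence[float] | None = None,
    seed: int = 0,
) -> str:
    """A random protein sequence guaranteed to match ``pattern``.

    Constrained positions are drawn uniformly from their allowed class;
    wildcard positions and the two flanks are drawn from the background
    composition (default uniform over the 20 residues).
    """
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    left, right = flank_lengths
    if left < 0 or right < 0:
        raise ValueError("flank lengths must be >= 0")
    bg = _uniform_background() if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    core: list[str] = []
    for elem in pattern.elements:
        if elem.kind == "wildcard":
            core.append(str(rng.choice(_AA, p=bg)))
        else:
            allowed = sorted(elem.residues)
            core.append(str(allowed[rng.integers(len(allowed))]))
    seq = (
        "".join(_draw_background(rng, left, bg))
        + "".join(core)
        + "".join(_draw_background(rng, right, bg))
    )
    assert scan_sequence(seq, pattern), "generated sequence must match the pattern"
    return seq


def _constrained_sites(
    root: str, pattern: SignaturePattern
) -> dict[int, frozenset]:
    """0-based site -> allowed residue class, from the first match on root."""
    matches = scan_sequence(root, pattern)
    if not matches:
        raise ValueError("root sequence does not match the signature pattern")
    m = matches[0]
    sites: dict[int, frozenset] = {}
    for offset, elem in enumerate(pattern.elements):
        if elem.kind != "wildcard":
            sites[m.start - 1 + offset] = elem.residues
    return sites


def evolve_family(
    root: str, spec: FamilySpec
) -> tuple[dict[str, str], TreeNode]:
    """Evolve ``root`` down a tree; one sequence per leaf plus the true tree.

    Each branch applies, per site, a Poisson(rate × branch length) number of
    substitutions, each replacing the residue uniformly among the other 19.
    With ``preserve_signature``, sites under a class or literal constraint of
    the motif mutate only within their class, so the signature survives in
    every descendant (a literal site never changes).
    """
    if not root:
        raise ValueError("root sequence must be non-empty")
    tree = spec.tree if spec.tree is not None else star_tree(spec.n_leaves)
    constrained: dict[int, frozenset] = {}
    if spec.preserve_signature:
        pattern = spec.pattern if spec.pattern is not None else load_gip_signature()
        constrained = _constrained_sites(root, pattern)
    rng = np.random.default_rng(spec.seed)
    leaves: dict[str, str] = {}

    def mutate(seq: list[str], branch_length: float) -> list[str]:
        out = list(seq)
        lam = spec.substitution_rate * branch_length
        if lam <= 0:
            return out
        hits = rng.poisson(lam, size=len(out))
        for site in np.nonzero(hits)[0]:
            allowed = constrained.get(int(site))
            choices = sorted(allowed) if allowed is not None else _AA
            for _ in range(int(hits[site])):
                others = [a for a in choices if a != out[site]]
                if others:
                    out[site] = str(others[rng.integers(len(others))])
        return out

    def descend(node: TreeNode, seq: list[str]) -> None:
        for child in node.children:
            bl = child.length if child.length is not None else 1.0
            child_seq = mutate(seq, bl)
            if child.is_tip():
                name = child.name or f"t{len(leaves) + 1}"
                leaves[name] = "".join(child_seq)
            else:
                descend(child, child_seq)

    descend(tree, list(root.upper()))
    return leaves, tree


def gen_decoys(
    pattern: SignaturePattern,
    n: int,
    mode: str = "break_one_position",
    seed: int = 0,
    flank_lengths: tuple[int, int] = (0, 0),
    background: Sequence[float] | None = None,
) -> dict[str, str]:
    """Negative-control sequences for classifier specificity.

    ``break_one_position`` takes a freshly generated conformant sequence and
    replaces exactly one constrained position with a residue outside its
    class, then verifies the scanner finds no match. ``shuffle`` permutes a
    conformant sequence; a shuffle may still match by chance, so it carries no
    non-match guarantee.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in {"break_one_position", "shuffle"}:
        raise ValueError(f"unknown decoy mode {mode!r}")
    breakable = [
        i
        for i, e in enumerate(pattern.elements)
        if e.kind != "wildcard" and len(e.residues) < 20
    ]
    if mode == "break_one_position" and not breakable:
        raise ValueError(
            "pattern has an all-residue class at every position; cannot break"
        )
    rng = np.random.default_rng(seed)
    decoys: dict[str, str] = {}
    for i in range(n):
        sub_seed = int(rng.integers(2**31))
        conformant = gen_signature_sequence(
            pattern, flank_lengths, background, seed=sub_seed
        )
        if mode == "shuffle":
            chars = list(conformant)
            rng.shuffle(chars)
            decoys[f"decoy_{i + 1}"] = "".join(chars)
            continue
        left = flank_lengths[0]
        for _attempt in range(100):
            pos = breakable[rng.integers(len(breakable))]
            outside = sorted(AMINO_ACIDS - pattern.elements[pos].residues)
            broken = list(conformant)
            broken[left + pos] = str(outside[rng.integers(len(outside))])
            candidate = "".join(broken)
            if not scan_sequence(candidate, pattern):
                decoys[f"decoy_{i + 1}"] = candidate
                break
        else:  # pragma: no cover - only reachable with long matching flanks
            raise RuntimeError("could not produce a non-matching decoy")
    return decoys


def gen_cd_spectrum(basis: BasisSet, spec: SpectrumSpec) -> CDSpectrum:
    """Noisy mixture Σ_k f_k B_k(λ) + N(0, σ²) on the shared grid."""
    if len(spec.wavelengths) != len(basis.wavelengths) or not np.allclose(
        spec.wavelengths, basis.wavelengths
    ):
        raise ValueError("basis and spectrum wavelength grids differ")
    if len(spec.fractions) != basis.n_classes:
        raise ValueError("fraction vector length must equal the basis class count")
    rng = np.random.default_rng(spec.seed)
    clean = basis.matrix @ spec.fractions
    noise = rng.normal(0.0, spec.noise_sd, size=len(clean)) if spec.noise_sd else 0.0
    return CDSpectrum(
        wavelengths=spec.wavelengths.copy(), ellipticity=clean + noise
    )


def gen_point_pattern(spec: PointProcessSpec) -> PointPattern:
    """Sample a CSR, hard-core or Thomas-cluster pattern in the window."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.window
    area = spec.area_um2

    def uniform_points(k: int) -> np.ndarray:
        return rng.uniform([0, 0], [w, h], size=(k, 2))

    if spec.process == "csr":
        n = rng.poisson(spec.intensity * area)
        pts = uniform_points(n)
    elif spec.process == "hard-core":
        n = rng.poisson(spec.intensity * area)
        d2 = spec.hard_core_distance**2
        placed: list[np.ndarray] = []
        attempts = 0
        max_attempts = 1_000_000
        while len(placed) < n:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"hard-core packing infeasible: {spec.intensity}/um^2 with"
                    f" minimum distance {spec.hard_core_distance} nm not"
                    f" reached after {max_attempts} attempts"
                )
            cand = rng.uniform([0, 0], [w, h])
            if all(((cand - p) ** 2).sum() >= d2 for p in placed):
                placed.append(cand)
        pts = np.array(placed).reshape(-1, 2)
    else:  # thomas
        kappa = (
            spec.parent_intensity
            if spec.parent_intensity is not None
            else spec.intensity / spec.mean_offspring
        )
        n_parents = rng.poisson(kappa * area)
        parents = uniform_points(n_parents)
        children: list[np.ndarray] = []
        for p in parents:
            k = rng.poisson(spec.mean_offspring)
            if k:
                children.append(p + rng.normal(0.0, spec.offspring_sd, size=(k, 2)))
        pts = np.vstack(children) if children else np.empty((0, 2))
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        )
        pts = pts[inside]
    return PointPattern(points=pts, window=(w, h), condition=spec.process)
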