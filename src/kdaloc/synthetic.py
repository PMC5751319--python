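"""Seeded generators for labeled point clouds and PSSM profiles.

Every stage of the pipeline can be exercised without external downloads:

- :func:`make_blobs` produces isotropic Gaussian classes whose centers sit
  at a common mutual distance (a regular simplex), the textbook
  linearly-separable regime;
- :func:`make_rings` produces concentric noisy shells -- classes that are
  not linearly separable in the input space but become separable after a
  nonlinear kernel reduction, and, at zero noise in three dimensions, the
  degenerate all-points-on-a-sphere configuration that breaks edge
  selectors relying on local tangent planes;
- :func:`make_pssm` produces integer score profiles in the typical
  PSI-BLAST log-odds range;
- :func:`preset` bundles ready-made configurations, including scaled-down
  datasets shaped like the Gram-positive (4 classes) and Gram-negative
  (8 classes) subcellular-localization benchmarks.

All outputs are a pure function of their seed.
"""

from __future__ import annotations

import numpy as np

from .dataset import LabeledDataset
from .features import PSSMProfile, pse_pssm, pssm_s

__all__ = ["make_blobs", "make_rings", "make_pssm", "simplex_centers", "preset", "PRESETS"]


def simplex_centers(n_classes: int, dim: int, separation: float) -> np.ndarray:
    """Vertices of a regular simplex with pairwise distance ``separation``.

    Needs ``dim >= n_classes - 1``; extra coordinates are zero-padded.
    """
    C = n_classes
    if dim < C - 1:
        raise ValueError(f"dim={dim} too small for {C} mutually equidistant centers")
    # vertices of the regular simplex: e_i in R^C, centered, then an
    # orthonormal change of basis into the first C-1 coordinates
    E = np.eye(C) - 1.0 / C
    # rows of E span a (C-1)-dim subspace; orthonormalize via QR of E^T
    q, _ = np.linalg.qr(E.T)
    verts = E @ q[:, : C - 1]  # C x (C-1), pairwise distance sqrt(2)*scale
    verts *= separation / np.sqrt(2.0)
    out = np.zeros((C, dim))
    out[:, : C - 1] = verts
    return out


def make_blobs(
    n_classes: int = 2,
    n_per_class: int = 30,
    dim: int = 2,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Isotropic Gaussian classes with mutually equidistant centers."""
    if n_classes < 2 or n_per_class < 1 or dim < 1:
        raise ValueError("need n_classes >= 2, n_per_class >= 1, dim >= 1")
    rng = np.random.default_rng(seed)
    centers = simplex_centers(n_classes, dim, separation)
    X = np.concatenate(
        [c + noise_sd * rng.standard_normal((n_per_class, dim)) for c in centers]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    return LabeledDataset(X, y)


def make_rings(
    radii=(1.0, 2.0),
    n_per_class: int = 30,
    dim: int = 2,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> LabeledDataset:
    """Concentric classes on shells of the given radii plus Gaussian noise.

    The defaults put the shells close enough that class boundaries touch --
    the regime the edge/internal selection rules assume (a widely separated
    pair of rings has no samples with mixed neighborhoods, hence no edge
    samples).  With ``noise_sd=0`` every point of class c lies exactly at
    norm ``radii[c]``; ``dim=3`` then reproduces the degenerate
    spherical-surface configuration.  Radii must be strictly increasing.
    """
    radii = [float(r) for r in radii]
    if len(radii) < 2 or any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
        raise ValueError("radii must be positive and strictly increasing")
    if n_per_class < 1 or dim < 2:
        raise ValueError("need n_per_class >= 1 and dim >= 2")
    rng = np.random.default_rng(seed)
    parts = []
    for r in radii:
        v = rng.standard_normal((n_per_class, dim))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        parts.append(r * v + noise_sd * rng.standard_normal((n_per_class, dim)))
    y = np.repeat(np.arange(len(radii)), n_per_class)
    return LabeledDataset(np.concatenate(parts), y)


def make_pssm(
    length: int = 60,
    seed: int = 0,
    score_range: tuple[int, int] = (-10, 13),
) -> PSSMProfile:
    """Random integer-score profile in the typical PSI-BLAST log-odds range.

    The consensus sequence (row argmax) doubles as the profile's sequence.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    lo, hi = score_range
    if hi <= lo:
        raise ValueError("score_range must be (low, high) with high > low")
    rng = np.random.default_rng(seed)
    scores = rng.integers(lo, hi + 1, size=(length, 20)).astype(float)
    profile = PSSMProfile(scores)
    profile.sequence = profile.consensus()
    return profile


def _feature_dataset(
    n_classes: int,
    n_per_class: int,
    encoder: str,
    seed: int,
    length_range: tuple[int, int] = (60, 120),
) -> LabeledDataset:
    """Labeled dataset of encoded synthetic PSSM profiles.

    Class structure comes from class-specific score offsets so the encoded
    vectors cluster by class; the feature dimension is the encoder's
    (1000 for PsePSSM, 220 for PSSM-S), mirroring the shapes of the real
    benchmark sample sets.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    offsets = rng.normal(0.0, 3.0, size=(n_classes, 20))
    for c in range(n_classes):
        for _ in range(n_per_class):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            prof = make_pssm(L, seed=int(rng.integers(0, 2**31 - 1)))
            prof.scores = prof.scores + offsets[c]
            vec = pse_pssm(prof).to_array() if encoder == "psepssm" else pssm_s(prof).to_array()
            rows.append(vec)
            labels.append(c)
    return LabeledDataset(np.asarray(rows), np.asarray(labels))


PRESETS = {
    "demo-rings": lambda seed: make_rings(radii=(1.0, 2.0), n_per_class=30, dim=2, noise_sd=0.2, seed=seed),
    "demo-blobs": lambda seed: make_blobs(n_classes=3, n_per_class=20, dim=2, separation=6.0, noise_sd=1.0, seed=seed),
    "shell": lambda seed: make_rings(radii=(1.0, 1.6), n_per_class=30, dim=3, noise_sd=0.0, seed=seed),
    # scaled-down datasets with the class counts / feature dimensions of the
    # Gram-positive (4 locations) and Gram-negative (8 locations) benchmarks
    "gp-1000-like": lambda seed: _feature_dataset(4, 8, "psepssm", seed),
    "gp-220-like": lambda seed: _feature_dataset(4, 8, "pssm_s", seed),
    "gn-1000-like": lambda seed: _feature_dataset(8, 5, "psepssm", seed),
    "gn-220-like": lambda seed: _feature_dataset(8, 5, "pssm_s", seed),
}


def preset(name: str, seed: int = 0) -> LabeledDataset:
    """A ready-made synthetic dataset by preset name (see :data:`PRESETS`)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return factory(seed)
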