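"""Synthetic scCAS data with known structure for testing and benchmarks.

Two generators are provided.  ``simulate_gaussian_from_model`` draws data
directly from the latent-variable model (Gaussian observations around
``beta x + W h``), optionally planting a rare subpopulation whose
spike-and-slab indicators are switched on along one dedicated direction
that is orthogonal to the reference basis.  It is the ground truth for
moment checks and parameter-recovery tests.

``simulate_counts_with_rare_subpopulation`` emulates the raw-data regime:
sparse multinomial peak counts with type-specific accessible peak blocks,
variable sequencing depth, and a pseudo-bulk reference built from every
cell type except the rare one — the reference-incompleteness setting the
model is designed for.  The count model is a deliberate stand-in (the
model itself is fit to Gaussianized TF-IDF values), so end-to-end tests
assert recovery of the planted structure, not count-likelihood fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ra3.model import CovariateMatrix, HyperParams, intercept_only
from ra3.preprocess import PeakSet, RawCountMatrix
from ra3.reference import ReferenceSampleSet, aggregate_pseudobulk

__all__ = [
    "SyntheticTruth",
    "simulate_gaussian_from_model",
    "simulate_counts_with_rare_subpopulation",
    "add_donor_effect",
]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    cell_labels: np.ndarray
    rare_label: str
    donor_labels: np.ndarray
    W1_true: np.ndarray | None
    w_rare: np.ndarray | None
    sigma2_true: float | None
    beta_true: np.ndarray | None
    gamma_true: np.ndarray | None = None
    h_true: np.ndarray | None = None
    type_profiles: np.ndarray | None = None

    @property
    def rare_mask(self) -> np.ndarray:
        return np.asarray(self.cell_labels) == self.rare_label


def _random_orthonormal(p: int, k: int, rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    return q[:, :k]


def simulate_gaussian_from_model(
    n: int,
    p: int,
    hp: HyperParams,
    X: CovariateMatrix | None = None,
    beta_true: np.ndarray | None = None,
    sigma2_true: float = 1.0,
    alpha_true: float | None = None,
    rare_fraction: float | None = None,
    rare_offset: float = 12.0,
    seed: int = 0,
):
    """Draw (Y, truth) from the generative model.

    The combined loading matrix ``[W1 W2 W3]`` is a random orthonormal
    frame so each latent direction carries unit-norm signal
    (``alpha_true`` defaults to ``p``, under which prior draws of the free
    loadings have unit expected norm).  With ``rare_fraction`` set, a
    planted subpopulation of that size has its indicator on the first
    spike-and-slab component forced to 1 (slab) and everyone else to 0;
    otherwise indicators are iid Bernoulli(theta) as in the prior.
    """
    rng = np.random.default_rng(seed)
    K1, K2, K3, K = hp.K1, hp.K2, hp.K3, hp.K
    if X is None:
        X = intercept_only(n)
    if beta_true is None:
        beta_true = np.zeros((p, X.q))
    if alpha_true is None:
        alpha_true = float(p)

    frame = _random_orthonormal(p, K, rng)
    W1 = frame[:, :K1]
    # free loadings: prior draws N(0, 1/alpha) projected is overkill here —
    # unit-norm columns keep per-direction signal comparable to the prior mean
    W2 = frame[:, K1 : K1 + K2] * np.sqrt(p / alpha_true)
    W3 = frame[:, K1 + K2 :] * np.sqrt(p / alpha_true)
    W = np.hstack([W1, W2, W3])

    gamma = np.ones((K, n), dtype=np.int8)
    if rare_fraction is None:
        gamma[hp.spike_slab_rows()] = rng.random((K2, n)) < hp.theta
        cell_labels = np.array(["bulk"] * n, dtype=object)
        rare_label = "rare"
    else:
        n_rare = int(round(n * rare_fraction))
        rare_idx = rng.choice(n, size=n_rare, replace=False)
        g2 = np.zeros((K2, n), dtype=np.int8)
        g2[0, rare_idx] = 1
        gamma[hp.spike_slab_rows()] = g2
        cell_labels = np.array(["common"] * n, dtype=object)
        cell_labels[rare_idx] = "rare"
        rare_label = "rare"

    sd = np.ones((K, n))
    g2f = gamma[hp.spike_slab_rows()].astype(float)
    sd[hp.spike_slab_rows()] = (1 - g2f) * hp.tau0 + g2f * hp.tau1
    H = rng.standard_normal((K, n)) * sd
    if rare_fraction is not None:
        # a rare cell *type* loads coherently on its direction, same sign
        # for every planted cell (zero-mean slab draws would cancel across
        # cells).  The default offset of ~2.4 slab standard deviations puts
        # the planted eigenvalue safely above the spiked-covariance
        # detection edge (1 + sqrt(p/n))^2 at the sizes used in tests;
        # below that edge no method could find the direction.
        H[K1, :] = 0.0
        H[K1, rare_idx] = rare_offset + rng.standard_normal(n_rare)
    Y = beta_true @ X.X + W @ H + np.sqrt(sigma2_true) * rng.standard_normal((p, n))

    truth = SyntheticTruth(
        cell_labels=cell_labels,
        rare_label=rare_label,
        donor_labels=np.array(["donor_0"] * n, dtype=object),
        W1_true=W1,
        w_rare=(W2[:, 0] / np.linalg.norm(W2[:, 0])
                if np.linalg.norm(W2[:, 0]) > 0 else None),
        sigma2_true=sigma2_true,
        beta_true=beta_true,
        gamma_true=gamma,
        h_true=H,
    )
    return Y, truth


def _type_profiles(
    p: int,
    n_types: int,
    rng: np.random.Generator,
    block_boost: float,
    block_fraction: float,
    rare_block_fraction: float,
    rare_boost: float,
) -> np.ndarray:
    """Per-type multinomial peak weights: shared background + a private
    block of elevated peaks per type (``block_fraction`` of peaks each).

    The last (rare) type inherits the first common type's profile and
    differs from it only in a small private block (``rare_block_fraction``
    of peaks, boosted ``rare_boost``-fold).  Keeping each private block's
    extra read mass modest mirrors real accessibility profiles (most reads
    fall in peaks shared across types) and, for the rare type, makes the
    rare subpopulation nearly invisible along the axes a reference lacking
    it can provide while its private peaks remain individually strong —
    the regime the spike-and-slab component is designed for.
    """
    block = max(int(p * block_fraction), 1)
    rare_block = max(int(p * rare_block_fraction), 1)
    if n_types * block > p:
        raise ValueError(
            f"p = {p} too small for {n_types} blocks of {block} peaks"
        )
    base = rng.gamma(shape=1.0, scale=1.0, size=p) + 0.05
    profiles = np.tile(base, (n_types, 1))
    for t in range(n_types - 1):
        lo = t * block
        profiles[t, lo : lo + block] *= block_boost
    rare = n_types - 1
    profiles[rare] = profiles[0]
    profiles[rare, rare * block : rare * block + rare_block] *= rare_boost
    return profiles / profiles.sum(axis=1, keepdims=True)


def simulate_counts_with_rare_subpopulation(
    n: int,
    p: int,
    n_types: int = 5,
    rare_fraction: float = 0.08,
    depth: int = 1000,
    block_boost: float = 8.0,
    block_fraction: float = 0.05,
    rare_block_fraction: float = 0.04,
    rare_boost: float = 12.0,
    depth_sigma: float = 0.3,
    ref_cells_per_type: int = 50,
    seed: int = 0,
):
    """Sparse count matrix with a rare type withheld from the reference.

    The last type is the rare one: ``round(n * rare_fraction)`` cells, the
    rest split evenly.  Per-cell depth is lognormal around ``depth`` and
    counts are multinomial over the type profile.  The returned reference
    is a pseudo-bulk average of independently simulated cells from every
    type except the rare one (``n_types - 1`` samples over the same
    peaks).
    """
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if not 0 < rare_fraction < 0.5:
        raise ValueError("rare_fraction must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    profiles = _type_profiles(
        p, n_types, rng, block_boost, block_fraction, rare_block_fraction, rare_boost
    )
    type_names = [f"type_{t}" for t in range(n_types - 1)] + ["rare"]

    n_rare = int(round(n * rare_fraction))
    n_common = n - n_rare
    sizes = [n_common // (n_types - 1)] * (n_types - 1)
    sizes[0] += n_common - sum(sizes)
    sizes.append(n_rare)
    labels = np.concatenate(
        [np.repeat(type_names[t], sizes[t]) for t in range(n_types)]
    ).astype(object)
    perm = rng.permutation(n)
    labels = labels[perm]

    def _sample_cells(cell_types: np.ndarray) -> sp.csr_matrix:
        cols = []
        depths = np.maximum(
            rng.lognormal(mean=np.log(depth), sigma=depth_sigma, size=len(cell_types)), 50
        ).astype(int)
        for t, d in zip(cell_types, depths):
            cols.append(rng.multinomial(d, profiles[t]))
        return sp.csr_matrix(np.array(cols).T)

    type_index = {name: t for t, name in enumerate(type_names)}
    counts = _sample_cells(np.array([type_index[l] for l in labels]))
    peaks = PeakSet(
        np.array(["chr1"] * p, dtype=object),
        np.arange(p) * 1000,
        np.arange(p) * 1000 + 500,
    )
    cell_ids = np.array([f"cell_{i}" for i in range(n)], dtype=object)
    sc = RawCountMatrix(counts, peaks, cell_ids)

    # independent reference cells for every non-rare type, binarized to
    # accessibility indicators and averaged per type: pseudo-bulk rows are
    # per-peak detection rates, the same space the binarized TF-IDF
    # normalization of the single-cell data lives in
    ref_types = np.repeat(np.arange(n_types - 1), ref_cells_per_type)
    ref_counts = _sample_cells(ref_types)
    ref_counts.data = np.ones_like(ref_counts.data)
    ref_labels = np.array([type_names[t] for t in ref_types], dtype=object)
    ref_ids = np.array([f"ref_{i}" for i in range(len(ref_types))], dtype=object)
    ref_sc = RawCountMatrix(ref_counts, peaks, ref_ids)
    reference = aggregate_pseudobulk(ref_sc, ref_labels)

    truth = SyntheticTruth(
        cell_labels=labels,
        rare_label="rare",
        donor_labels=np.array(["donor_0"] * n, dtype=object),
        W1_true=None,
        w_rare=None,
        sigma2_true=None,
        beta_true=None,
        type_profiles=profiles,
    )
    return sc, truth, reference


def add_donor_effect(
    data,
    donor_labels,
    effect_size: float,
    seed: int = 0,
    peak_fraction: float = 0.3,
):
    """Plant a donor-specific technical effect so covariate adjustment is testable.

    Count input (:class:`RawCountMatrix`): for each donor a private random
    subset of peaks (``peak_fraction`` of them) is binomially thinned with
    keep probability ``1 / (1 + effect_size)`` — a donor-specific loss of
    accessibility that survives binarization, mimicking batch-varying
    assay efficiency.  Dense/Gaussian input: each donor adds
    ``effect_size`` times a fixed random peak vector.  ``effect_size = 0``
    returns the input unchanged.
    """
    donor_labels = np.asarray(donor_labels, dtype=object)
    donors = sorted(set(donor_labels))
    if len(donors) < 2:
        raise ValueError("need at least two donors")
    rng = np.random.default_rng(seed)
    if isinstance(data, RawCountMatrix):
        if effect_size == 0:
            return data
        dense = np.asarray(data.counts.todense()).astype(np.int64)
        p = dense.shape[0]
        keep = 1.0 / (1.0 + effect_size)
        for d in donors:
            cells = donor_labels == d
            peaks_d = rng.random(p) < peak_fraction
            block = dense[np.ix_(peaks_d, cells)]
            dense[np.ix_(peaks_d, cells)] = rng.binomial(block, keep)
        return RawCountMatrix(sp.csr_matrix(dense), data.peaks, data.cell_ids)
    mat = np.array(data, dtype=np.float64, copy=True)
    if effect_size == 0:
        return mat
    p = mat.shape[0]
    for d in donors:
        shift = effect_size * rng.standard_normal(p)
        mat[:, donor_labels == d] += shift[:, None]
    return mat
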