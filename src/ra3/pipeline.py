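"""End-to-end workflows: preprocess -> reference -> fit -> cluster.

These helpers wire the modules together the way the CLI (and the
benchmark experiments) use them, including the two baselines the model is
compared against: projecting cells onto the reference basis alone, and
plain PCA of the TF-IDF matrix.
"""

from __future__ import annotations

import numpy as np

from ra3 import downstream, model, preprocess, reference, synthetic

__all__ = [
    "prepare",
    "fit_ra3",
    "baseline_tfidf_pca",
    "rare_type_experiment",
    "donor_covariate_experiment",
    "dropout_experiment",
]


def prepare(
    counts: preprocess.RawCountMatrix,
    ref: reference.ReferenceSampleSet,
    min_cell_fraction: float = 0.03,
    k1_cap: int = 30,
    standardize: bool = True,
    match_reference_transform: bool = True,
):
    """Feature-select, TF-IDF-normalize, subset the reference to the
    retained peaks, and learn the projection basis.

    The model's priors fix an absolute scale for the data: scores on the
    reference-shared directions carry a standard-normal prior, while the
    slab is meant for scores several prior standard deviations out.  With
    ``standardize`` (default) the normalized matrix is therefore divided
    by one global scalar — the standard deviation of the cells' scores on
    the reference basis — so that shared variation is O(1) on the prior's
    scale.  Raw TF-IDF entries are orders of magnitude smaller (every
    score would sit in the spike); conversely, leaving shared scores much
    wider than the prior makes the standard-normal prior shrink them and
    the leftover shared structure is absorbed, cell by cell, by the
    spike-and-slab component.  A single positive scalar changes neither
    zero preservation nor per-cell depth invariance.

    With ``match_reference_transform`` (default) reference rows are
    depth-normalized and weighted by the single-cell IDF before PCA, so
    the basis spans the shared-variation directions of the space the model
    is actually fit in.  A basis learned on raw reference values is
    misaligned with the TF-IDF-weighted single-cell space, which lets
    shared variation leak into the residual and be absorbed by the
    spike-and-slab component.
    """
    filtered, mask = preprocess.select_features(counts, min_cell_fraction)
    Y = preprocess.tfidf_transform(filtered)
    ref_vals = ref.values[:, mask]
    if match_reference_transform:
        totals = ref_vals.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("a reference sample has zero signal on the retained peaks")
        df = filtered.counts.getnnz(axis=1)
        idf = np.log1p(filtered.n_cells / df)
        ref_vals = ref_vals / totals * idf
    ref_matched = reference.ReferenceSampleSet(
        ref_vals, ref.sample_ids, ref.provenance
    )
    basis = reference.learn_projection(ref_matched, k1_cap)
    if standardize:
        scores = reference.bulk_project(Y, basis)
        scale = float(scores.std())
        if scale <= 0:
            raise ValueError("degenerate data: zero variance on the reference basis")
        Y = preprocess.NormalizedMatrix(Y.values / scale, Y.source_peaks, Y.cell_ids)
    return Y, basis, mask


def fit_ra3(
    Y: preprocess.NormalizedMatrix,
    basis: reference.ProjectionBasis,
    covariates: model.CovariateMatrix | None = None,
    seed: int = 0,
    **hp_overrides,
) -> model.FitResult:
    hp = model.HyperParams(K1=basis.K1, seed=seed, **hp_overrides)
    return model.fit(Y, covariates, basis, hp)


def baseline_tfidf_pca(Y: preprocess.NormalizedMatrix, n_components: int = 10) -> np.ndarray:
    """TF-IDF + PCA baseline: top principal-component scores (components x cells)."""
    dense = Y.dense()
    centered = dense - dense.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    return vt[:k] * s[:k, None]


def _gamma_sens_spec(state: model.ModelState, hp: model.HyperParams, rare_mask) -> tuple:
    """Best sensitivity/specificity over spike-and-slab rows for flagging
    the rare cells with gamma = 1."""
    rare_mask = np.asarray(rare_mask, dtype=bool)
    best = (-1.0, 0.0, 0.0)
    for row in state.Gamma[hp.spike_slab_rows()]:
        flagged = row.astype(bool)
        sens = flagged[rare_mask].mean() if rare_mask.any() else 0.0
        spec = (~flagged[~rare_mask]).mean() if (~rare_mask).any() else 0.0
        if sens + spec > best[0]:
            best = (sens + spec, float(sens), float(spec))
    return best[1], best[2]


def rare_type_experiment(
    seed: int,
    n: int = 1000,
    p: int = 2000,
    n_types: int = 5,
    rare_fraction: float = 0.08,
    target_k: int | None = None,
    max_iter: int = 400,
    dropout_rate: float = 0.0,
) -> dict:
    """Full-pipeline benchmark on one counts-with-rare-type simulation.

    Fits the model on data whose rare type is absent from the reference
    and clusters the latent representation, alongside the bulk-projection
    and TF-IDF+PCA baselines clustered identically.  Returns AMI against
    the true cell types for all three, plus rare-cell sensitivity and
    specificity of the spike-and-slab indicators.
    """
    target_k = target_k or n_types
    counts, truth, ref = synthetic.simulate_counts_with_rare_subpopulation(
        n=n, p=p, n_types=n_types, rare_fraction=rare_fraction, seed=seed
    )
    if dropout_rate > 0:
        counts = preprocess.downsample_counts(counts, dropout_rate, seed=seed + 1)
    Y, basis, _ = prepare(counts, ref)
    result = fit_ra3(Y, basis, seed=seed, max_iter=max_iter)
    latent = model.latent_representation(result)

    def _ami(rep, scaling=True) -> float:
        clusters = downstream.louvain_with_target_k(
            rep, target_k, seed=seed, standardize=scaling
        )
        return downstream.external_cluster_metrics(truth.cell_labels, clusters.labels).ami

    ami_ra3 = _ami(latent, scaling="cap")
    ami_bulk = _ami(reference.bulk_project(Y, basis))
    ami_pca = _ami(baseline_tfidf_pca(Y))
    hp = model.HyperParams(K1=basis.K1, seed=seed, max_iter=max_iter)
    sens, spec = _gamma_sens_spec(result.state, hp, truth.rare_mask)
    return {
        "ami_ra3": ami_ra3,
        "ami_bulk_projection": ami_bulk,
        "ami_tfidf_pca": ami_pca,
        "gamma_sensitivity": sens,
        "gamma_specificity": spec,
        "n_iterations": result.n_iterations,
        "converged": result.converged,
    }


def donor_covariate_experiment(
    seed: int,
    n: int = 600,
    p: int = 1200,
    n_types: int = 4,
    n_donors: int = 2,
    effect_size: float = 6.0,
    peak_fraction: float = 0.5,
    max_iter: int = 400,
) -> dict:
    """A/B comparison of fitting with versus without donor covariates.

    A donor-specific accessibility bias is planted (donors assigned
    independently of cell type; half the peaks thinned ~7-fold for one
    donor — severe confounding, beyond what the technical-variation
    component absorbs unaided), then the model is fit twice on identical
    data: once with donor indicators in the design matrix, once with the
    intercept alone.  Returns the AMI against cell-type truth for both.
    """
    counts, truth, ref = synthetic.simulate_counts_with_rare_subpopulation(
        n=n, p=p, n_types=n_types, seed=seed
    )
    rng = np.random.default_rng(seed + 10_000)
    donors = np.array([f"donor_{d}" for d in rng.integers(0, n_donors, n)], dtype=object)
    counts = synthetic.add_donor_effect(
        counts, donors, effect_size, seed=seed + 1, peak_fraction=peak_fraction
    )
    Y, basis, _ = prepare(counts, ref)

    levels = sorted(set(donors))
    rows = [np.ones(n)] + [(donors == lev).astype(float) for lev in levels[1:]]
    X = model.CovariateMatrix(np.vstack(rows), ["intercept"] + levels[1:])

    def _ami(result) -> float:
        latent = model.latent_representation(result)
        clusters = downstream.louvain_with_target_k(
            latent, n_types, seed=seed, standardize="cap"
        )
        return downstream.external_cluster_metrics(truth.cell_labels, clusters.labels).ami

    with_cov = _ami(fit_ra3(Y, basis, covariates=X, seed=seed, max_iter=max_iter))
    without_cov = _ami(fit_ra3(Y, basis, covariates=None, seed=seed, max_iter=max_iter))
    return {"ami_with_covariates": with_cov, "ami_without_covariates": without_cov}


def dropout_experiment(
    seed: int,
    rates=(0.05, 0.25, 0.5),
    n: int = 800,
    p: int = 1600,
    n_types: int = 5,
    max_iter: int = 400,
) -> dict:
    """Robustness of the model versus TF-IDF+PCA under read dropout.

    Nonzero counts are dropped at each rate before the full pipeline runs;
    AMI against cell-type truth is reported for the model and the PCA
    baseline at every rate.
    """
    out = {}
    for rate in rates:
        res = rare_type_experiment(
            seed=seed, n=n, p=p, n_types=n_types, max_iter=max_iter, dropout_rate=rate
        )
        out[rate] = {
            "ami_ra3": res["ami_ra3"],
            "ami_tfidf_pca": res["ami_tfidf_pca"],
        }
    return out
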