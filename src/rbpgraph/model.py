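"""High-level modelling interface.

:class:`RBPBindingModel` bundles a set of target sites with the encoding
choices (sequence-only or full structure, folding and kernel parameters) and
exposes ``fit``, ``cross_validate`` and ``line_search``;  ``fit`` returns an
:class:`RBPBindingResults` carrying the trained weights, training
diagnostics, a ``summary()`` table and the downstream applications
(prediction margins, per-nucleotide profiles, site calls, motifs).
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import spearmanr

from . import learn, profiles
from .encode import encode_site
from .folding import FoldingParams, fold_context
from .kernel import KernelParams, extract_features, vectors_to_csr
from .learn import (ClassifierParams, CVResult, LinearModel, RegressionParams,
                    auroc, average_precision, crossvalidate)
from .prep import TargetSite


class RBPBindingModel:
    """A binding-preference model specification over a set of target sites.

    Parameters
    ----------
    sites
        Training sites; each must carry a +1/-1 label (classification) or a
        continuous affinity (regression), consistently across the set.
    mode
        "sequence" encodes the nucleotide chain only; "structure" folds each
        context into shreps and adds base pairs and the abstract layer.
    """

    def __init__(self, sites: Sequence[TargetSite], mode: str = "sequence",
                 folding_params: FoldingParams | None = None,
                 kernel_params: KernelParams | None = None,
                 backend=None):
        if not sites:
            raise ValueError("no training sites")
        if mode not in ("sequence", "structure"):
            raise ValueError("mode must be 'sequence' or 'structure'")
        self.sites = list(sites)
        self.mode = mode
        self.folding_params = folding_params or FoldingParams()
        self.kernel_params = kernel_params or KernelParams()
        self.backend = backend
        labels = [s.label for s in self.sites]
        affinities = [s.affinity for s in self.sites]
        if all(l is not None for l in labels):
            self.task = "classification"
            self.y = np.asarray(labels, dtype=np.float64)
        elif all(a is not None for a in affinities):
            self.task = "regression"
            self.y = np.asarray(affinities, dtype=np.float64)
        else:
            raise ValueError("sites must uniformly carry labels or affinities")
        self._X: sparse.csr_matrix | None = None
        self._hypotheses: list | None = None

    # -- encoding ----------------------------------------------------------
    def hypotheses_for(self, site: TargetSite):
        if self.mode == "sequence":
            return None
        return fold_context(site.context_sequence, self.folding_params, self.backend)

    @property
    def hypotheses(self) -> list:
        if self._hypotheses is None:
            self._hypotheses = [self.hypotheses_for(s) for s in self.sites]
        return self._hypotheses

    @property
    def exog(self) -> sparse.csr_matrix:
        """The hashed design matrix (encoded lazily, then cached)."""
        if self._X is None:
            hyps = self.hypotheses if self.mode == "structure" else [None] * len(self.sites)
            vecs = [extract_features(encode_site(s, h, mode=self.mode), self.kernel_params)
                    for s, h in zip(self.sites, hyps)]
            self._X = vectors_to_csr(vecs, self.kernel_params)
        return self._X

    def vectorize(self, sites: Sequence[TargetSite]) -> sparse.csr_matrix:
        vecs = [extract_features(
            encode_site(s, self.hypotheses_for(s), mode=self.mode), self.kernel_params)
            for s in sites]
        return vectors_to_csr(vecs, self.kernel_params)

    # -- fitting -----------------------------------------------------------
    def fit(self, params: ClassifierParams | RegressionParams | None = None,
            seed: int = 0) -> "RBPBindingResults":
        if self.task == "classification":
            params = params or ClassifierParams(seed=seed)
            inner = learn.train_classifier(self.exog, self.y, params,
                                           self.kernel_params, self.mode)
        else:
            params = params or RegressionParams()
            inner = learn.train_regressor(self.exog, self.y, params,
                                          self.kernel_params, self.mode)
        return RBPBindingResults(self, inner, params)

    def cross_validate(self, params: ClassifierParams | None = None,
                       k: int = 10, seed: int = 0) -> CVResult:
        if self.task != "classification":
            raise ValueError("cross_validate applies to classification tasks")
        params = params or ClassifierParams(seed=seed)
        return crossvalidate(self.exog, self.y, params, k=k, seed=seed,
                             kernel_params=self.kernel_params)

    def line_search(self, grids: Mapping[str, Sequence], seed: int = 0,
                    cv_k: int = 5) -> tuple[ClassifierParams, np.ndarray, float]:
        """Round-robin hyperparameter fit on a held-aside tuning subset of
        min(1000, 10% of n) examples; returns (params, assessment indices,
        tuning score)."""
        return learn.line_search_classifier(self.exog, self.y, grids, seed=seed,
                                            cv_k=cv_k, kernel_params=self.kernel_params)


class RBPBindingResults:
    """Fitted binding model: weights, diagnostics and applications."""

    def __init__(self, model: RBPBindingModel, inner: LinearModel, params):
        self.model = model
        self.inner = inner
        self.params = params
        self.train_margins = inner.margin(model.exog)

    # -- core accessors ----------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        return self.inner.weights

    @property
    def bias(self) -> float:
        return self.inner.bias

    # -- prediction --------------------------------------------------------
    def predict_margin(self, sites: Sequence[TargetSite] | None = None) -> np.ndarray:
        """Signed margins: positive predicts binding, magnitude tracks affinity."""
        if sites is None:
            return self.train_margins
        return self.inner.margin(self.model.vectorize(sites))

    predict_affinity = predict_margin

    def profile(self, site: TargetSite) -> profiles.PredictionProfile:
        return profiles.profile_site(self.inner, site,
                                     self.model.hypotheses_for(site))

    def motif(self, sites: Sequence[TargetSite] | None = None, k: int = 12,
              top_n: int = 1000) -> profiles.Motif:
        model = self.model
        if sites is None:
            if model.task == "classification":
                sites = [s for s in model.sites if s.label == 1]
            else:
                sites = model.sites
        hyps = [model.hypotheses_for(s) or
                fold_context(s.context_sequence, model.folding_params, model.backend)
                for s in sites]
        return profiles.extract_motif(self.inner, sites, hyps, k=k, top_n=top_n)

    # -- diagnostics -------------------------------------------------------
    def train_metrics(self) -> dict[str, float]:
        m = self.train_margins
        if self.model.task == "classification":
            return {"auroc": auroc(m, self.model.y),
                    "average_precision": average_precision(m, self.model.y)}
        rho = spearmanr(m, self.model.y).statistic
        rmse = float(np.sqrt(np.mean((m - self.model.y) ** 2)))
        return {"spearman": float(rho), "rmse": rmse}

    def summary(self) -> str:
        model = self.model
        lines = [
            "RBP binding preference model",
            "=" * 34,
            f"task:            {model.task}",
            f"encoding mode:   {model.mode}",
            f"n sites:         {len(model.sites)}",
            f"kernel:          R={model.kernel_params.R} D={model.kernel_params.D} "
            f"bits={model.kernel_params.bits}",
        ]
        if model.mode == "structure":
            fp = model.folding_params
            lines.append(f"folding:         window={fp.window_len} step={fp.step} "
                         f"shreps<={fp.max_shreps_per_window} band={fp.energy_band} "
                         f"abstraction={fp.abstraction_level}")
        lines.append(f"fit params:      {asdict(self.params)}")
        lines.append(f"nonzero weights: {int(np.count_nonzero(self.weights))}")
        lines.append(f"bias:            {self.bias:.6g}")
        for name, value in self.train_metrics().items():
            lines.append(f"train {name:<18s} {value:.4f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        self.inner.save(path)

    @staticmethod
    def load_linear(path) -> LinearModel:
        return LinearModel.load(path)
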