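"""Case/control DNA-methylation episignature construction and
correlation-based classification.

An episignature is a set of CpGs whose beta values (methylation levels in
[0, 1]) jointly separate carriers of a molecular lesion (e.g. NSD1 loss of
function in Sotos syndrome) from controls. The signature is built from a
random subsample of 15 cases and 15 controls: per CpG, the effect size is
the difference of group mean betas and the p-value a Welch two-sample
t-test, Benjamini-Hochberg adjusted; signature CpGs satisfy
|delta beta| >= 0.20 and adjusted p <= 0.01. A query sample is classified
by Pearson correlation of its betas at the signature CpGs against the mean
case and mean control profiles; samples used to build the signature are
excluded from evaluation.

The estimator follows scikit-learn conventions (fit/predict/get_params,
fitted attributes with a trailing underscore) and composes with sklearn
model selection; thin module-level functions wrap it for table-based use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

EFFECT_CUTOFF = 0.20
FDR_CUTOFF = 0.01
TRAIN_PER_GROUP = 15
MIN_COVERAGE = 0.90


@dataclass
class Signature:
    """Differentially methylated CpG set with per-CpG group means."""

    cpg_ids: np.ndarray
    case_mean: np.ndarray
    control_mean: np.ndarray
    effect: np.ndarray          # case mean - control mean
    qvalue: np.ndarray          # BH-adjusted p

    def __len__(self) -> int:
        return len(self.cpg_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cpg": self.cpg_ids, "case_mean": self.case_mean,
                             "control_mean": self.control_mean,
                             "delta_beta": self.effect, "qvalue": self.qvalue})


class MethylationSignatureClassifier(BaseEstimator, ClassifierMixin):
    """Episignature classifier: differential-CpG selection + correlation.

    Parameters
    ----------
    effect_cutoff : minimum |delta beta| for a signature CpG (default 0.20).
    fdr : Benjamini-Hochberg adjusted-p cutoff (default 0.01).
    n_train_per_group : cases and controls subsampled to build the
        signature (default 15, the published protocol).
    min_coverage : fraction of signature CpGs a query must cover.
    random_state : seed for the case/control subsample.

    Attributes
    ----------
    signature_ : Signature of selected CpGs.
    case_profile_, control_profile_ : mean beta profiles at signature CpGs.
    train_mask_ : boolean mask over fit samples marking those consumed in
        signature construction (to be excluded from evaluation).
    classes_ : array(["case", "control"]).
    """

    def __init__(self, effect_cutoff: float = EFFECT_CUTOFF,
                 fdr: float = FDR_CUTOFF,
                 n_train_per_group: int = TRAIN_PER_GROUP,
                 min_coverage: float = MIN_COVERAGE,
                 random_state: Optional[int] = None):
        self.effect_cutoff = effect_cutoff
        self.fdr = fdr
        self.n_train_per_group = n_train_per_group
        self.min_coverage = min_coverage
        self.random_state = random_state

    def fit(self, X, y, cpg_ids: Optional[Sequence[str]] = None):
        """Build the signature from betas X (n_samples, n_cpgs) and labels
        y in {"case", "control"}."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_cpgs) matching y")
        if np.any((X < 0) | (X > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        case_idx = np.flatnonzero(y == "case")
        ctrl_idx = np.flatnonzero(y == "control")
        k = self.n_train_per_group
        if len(case_idx) < k or len(ctrl_idx) < k:
            raise ValueError(f"need >= {k} cases and >= {k} controls; "
                             f"got {len(case_idx)}/{len(ctrl_idx)}")
        rng = np.random.default_rng(self.random_state)
        case_tr = rng.choice(case_idx, size=k, replace=False)
        ctrl_tr = rng.choice(ctrl_idx, size=k, replace=False)
        self.train_mask_ = np.zeros(X.shape[0], dtype=bool)
        self.train_mask_[case_tr] = True
        self.train_mask_[ctrl_tr] = True

        xc = X[case_tr]
        xk = X[ctrl_tr]
        effect = xc.mean(axis=0) - xk.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(xc, xk, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        qvals = stats.false_discovery_control(pvals, method="bh")
        sel = (np.abs(effect) >= self.effect_cutoff) & (qvals <= self.fdr)

        ids = (np.asarray(cpg_ids) if cpg_ids is not None
               else np.arange(X.shape[1]))
        self.cpg_ids_ = ids
        self.signature_ = Signature(ids[sel], xc.mean(axis=0)[sel],
                                    xk.mean(axis=0)[sel], effect[sel],
                                    qvals[sel])
        self.case_profile_ = xc.mean(axis=0)[sel]
        self.control_profile_ = xk.mean(axis=0)[sel]
        self._sel_idx = np.flatnonzero(sel)
        self.classes_ = np.array(["case", "control"])
        return self

    def correlations(self, X) -> np.ndarray:
        """Pearson r of each query against (case, control) mean profiles
        at the signature CpGs; returns (n_samples, 2)."""
        check_is_fitted(self, "signature_")
        if len(self.signature_) == 0:
            raise ValueError("empty signature: no CpGs passed the cutoffs")
        X = np.asarray(X, dtype=float)
        sub = X[:, self._sel_idx]
        finite = np.isfinite(sub)
        out = np.empty((X.shape[0], 2))
        for i in range(X.shape[0]):
            mask = finite[i]
            if mask.mean() < self.min_coverage:
                raise ValueError(f"query {i} covers {mask.mean():.0%} of "
                                 f"signature CpGs (< {self.min_coverage:.0%})")
            out[i, 0] = stats.pearsonr(sub[i, mask], self.case_profile_[mask])[0]
            out[i, 1] = stats.pearsonr(sub[i, mask], self.control_profile_[mask])[0]
        return out

    def predict(self, X) -> np.ndarray:
        """Label each query case/control by the larger correlation;
        exact ties are labelled "uncertain"."""
        r = self.correlations(X)
        labels = np.where(r[:, 0] > r[:, 1], "case",
                          np.where(r[:, 1] > r[:, 0], "control", "uncertain"))
        return labels


def build_signature(betas: pd.DataFrame, labels,
                    effect_cutoff: float = EFFECT_CUTOFF,
                    fdr: float = FDR_CUTOFF,
                    n_per_group: int = TRAIN_PER_GROUP,
                    seed: Optional[int] = None,
                    ) -> Tuple[Signature, MethylationSignatureClassifier]:
    """Table-level wrapper: ``betas`` is CpG x sample, ``labels`` maps
    sample -> case/control. Returns (signature, fitted classifier)."""
    labels = pd.Series(labels)
    samples = [s for s in betas.columns if labels.get(s) in ("case", "control")]
    X = betas[samples].to_numpy().T
    y = labels[samples].to_numpy()
    clf = MethylationSignatureClassifier(effect_cutoff=effect_cutoff, fdr=fdr,
                                         n_train_per_group=n_per_group,
                                         random_state=seed)
    clf.fit(X, y, cpg_ids=betas.index.to_numpy())
    return clf.signature_, clf


def classify_by_correlation(query: pd.Series, signature: Signature,
                            min_coverage: float = MIN_COVERAGE,
                            ) -> Tuple[str, float, float]:
    """Classify one query beta vector (indexed by CpG id) against a
    signature. Returns (label, r_case, r_control)."""
    if len(signature) == 0:
        raise ValueError("empty signature")
    present = query.reindex(signature.cpg_ids)
    mask = present.notna().to_numpy()
    if mask.mean() < min_coverage:
        raise ValueError(f"query covers {mask.mean():.0%} of signature CpGs")
    vals = present.to_numpy(dtype=float)[mask]
    r_case = float(stats.pearsonr(vals, signature.case_mean[mask])[0])
    r_ctrl = float(stats.pearsonr(vals, signature.control_mean[mask])[0])
    if r_case > r_ctrl:
        return "case", r_case, r_ctrl
    if r_ctrl > r_case:
        return "control", r_case, r_ctrl
    return "uncertain", r_case, r_ctrl
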