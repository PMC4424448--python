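"""Scikit-learn-style estimators wrapping the analysis pipeline.

:class:`TernaryDiscretizer` is a transformer: fit on reference (control)
samples, transform any expression matrix into the ternary {-1, 0, +1}
gene-activity indicator. :class:`CoreRegulationAnalysis` is the end-to-end
estimator: fit on a samples × genes log2 expression frame with group labels
(the reserved label marking the controls) and obtain per-group core
regulation sets, frequency tables and sample networks as fitted attributes.

Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``clone``-ability) so the
discretizer composes with pipelines and model selection.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import core as _core
from . import expression as _expr
from .core import CoreRegulationSet, FrequencyTable, ValidationResult
from .network import RegulatoryNetwork
from .sample_networks import RegulationInstance, SampleNetwork, induce_all

__all__ = ["TernaryDiscretizer", "CoreRegulationAnalysis"]


class TernaryDiscretizer(TransformerMixin, BaseEstimator):
    """Discretize expression to {-1, 0, +1} against a reference mean.

    Fit learns the per-gene mean of the reference samples; transform maps a
    samples × genes matrix (log2 scale) to +1 where the log2 fold change
    versus that mean is at least ``log2(cutoff)``, -1 where it is at most
    ``-log2(cutoff)``, and 0 otherwise (missing values included).

    Parameters
    ----------
    cutoff : float, default=2.0
        Linear-scale fold-change threshold K (must exceed 1); the default
        calls a gene at a two-fold change.

    Attributes
    ----------
    reference_mean_ : ndarray of shape (n_genes,)
        Per-gene mean of the reference samples (NaN-aware).
    n_features_in_ : int
    feature_names_in_ : ndarray of str, present when fit on a DataFrame.

    Examples
    --------
    >>> import numpy as np
    >>> ref = np.array([[2.0, 5.0], [2.0, 5.0]])
    >>> disc = TernaryDiscretizer(cutoff=2.0).fit(ref)
    >>> disc.transform(np.array([[3.5, 3.5]]))
    array([[ 1, -1]], dtype=int8)
    """

    def __init__(self, cutoff: float = 2.0):
        self.cutoff = cutoff

    def fit(self, X, y=None) -> "TernaryDiscretizer":
        if not self.cutoff > 1:
            raise ValueError(
                f"fold-change cutoff must be > 1, got {self.cutoff}"
            )
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        self.n_features_in_ = values.shape[1]
        self.reference_mean_ = np.nanmean(values, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_mean_")
        is_frame = isinstance(X, pd.DataFrame)
        if is_frame:
            values = X.to_numpy(dtype=float)
            index, columns = X.index, X.columns
        else:
            values = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        if values.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {values.shape[1]} features, expected {self.n_features_in_}"
            )
        fc = values - self.reference_mean_
        thr = math.log2(self.cutoff)
        out = np.zeros(fc.shape, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            out[fc >= thr] = 1
            out[fc <= -thr] = -1
        if is_frame:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "reference_mean_")
        if input_features is not None:
            return np.asarray(input_features, dtype=object)
        if hasattr(self, "feature_names_in_"):
            return self.feature_names_in_
        return np.asarray(
            [f"x{i}" for i in range(self.n_features_in_)], dtype=object
        )


class CoreRegulationAnalysis(BaseEstimator):
    """Sample-specific regulation networks and per-group core regulations.

    Fit takes a samples × genes expression DataFrame on the log2 scale
    (columns named by gene symbol so they can be matched to the prior
    network) and a vector of group labels, one per sample, with
    ``reference_label`` marking the controls. It discretizes every
    non-reference sample against the control mean, overlays each indicator
    column on the prior network keeping only sign-consistent regulations,
    tallies instance frequencies per group, and thresholds at ``threshold``
    to obtain each group's core regulation set (with subnetwork component
    labels filled in).

    Parameters
    ----------
    network : RegulatoryNetwork
        The prior signed regulatory network.
    cutoff : float, default=2.0
        Linear fold-change threshold K for the ternary indicator.
    threshold : float, default=0.5
        Core-membership prevalence threshold T in (0, 1].
    reference_label : str, default="REFERENCE"
        Group label marking control samples.

    Attributes
    ----------
    discretizer_ : TernaryDiscretizer fitted on the reference samples.
    fold_change_ : DataFrame, genes × tumors log2 fold changes.
    indicator_ : DataFrame, genes × tumors ternary indicator.
    sample_networks_ : dict sample_id -> SampleNetwork.
    groups_ : list of group labels seen (reference excluded), input order.
    frequency_tables_ : dict group -> FrequencyTable.
    core_sets_ : dict group -> CoreRegulationSet (components labelled).
    """

    def __init__(
        self,
        network: RegulatoryNetwork | None = None,
        cutoff: float = 2.0,
        threshold: float = 0.5,
        reference_label: str = _expr.REFERENCE_LABEL,
    ):
        self.network = network
        self.cutoff = cutoff
        self.threshold = threshold
        self.reference_label = reference_label

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "CoreRegulationAnalysis":
        if not isinstance(self.network, RegulatoryNetwork):
            raise ValueError("a prior RegulatoryNetwork is required")
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a samples x genes DataFrame with gene-named columns"
            )
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        y = np.asarray(list(y), dtype=object)
        if len(y) != len(X):
            raise ValueError("y must provide one group label per sample")

        ref_mask = y == self.reference_label
        if not ref_mask.any():
            raise ValueError(
                f"no reference samples: no label equals {self.reference_label!r}"
            )
        if ref_mask.all():
            raise ValueError("all samples are references; nothing to analyse")

        self.discretizer_ = TernaryDiscretizer(cutoff=self.cutoff).fit(
            X.loc[ref_mask]
        )
        tumors = X.loc[~ref_mask]
        # genes x tumors orientation for the functional layer and exports
        self.fold_change_ = (
            tumors.to_numpy(dtype=float) - self.discretizer_.reference_mean_
        ).T
        self.fold_change_ = pd.DataFrame(
            self.fold_change_, index=X.columns, columns=tumors.index
        )
        self.indicator_ = self.discretizer_.transform(tumors).T

        nets = induce_all(self.network, self.indicator_)
        self.sample_networks_ = {sn.sample_id: sn for sn in nets}

        tumor_groups = y[~ref_mask]
        self.sample_groups_ = dict(zip(tumors.index, tumor_groups))
        self.groups_ = list(dict.fromkeys(tumor_groups))
        self.frequency_tables_ = {}
        self.core_sets_ = {}
        for group in self.groups_:
            group_nets = [
                sn for sn, g in zip(nets, tumor_groups) if g == group
            ]
            freq = _core.frequency_table(group_nets)
            core = _core.identify_core(freq, self.threshold, group_label=group)
            self.frequency_tables_[group] = freq
            self.core_sets_[group] = _core.find_subnetworks(core)
        return self

    # -- post-fit analyses -------------------------------------------------

    def core_set(self, group: str | None = None) -> CoreRegulationSet:
        check_is_fitted(self, "core_sets_")
        if group is None:
            if len(self.core_sets_) != 1:
                raise ValueError(
                    f"several groups fitted ({self.groups_}); name one"
                )
            group = self.groups_[0]
        return self.core_sets_[group]

    def group_specific(
        self,
        target: str,
        others: Iterable[str] | None = None,
        edge_level: bool = False,
    ) -> frozenset[RegulationInstance]:
        """Core instances of ``target`` absent from every other group's core."""
        check_is_fitted(self, "core_sets_")
        if others is None:
            others = [g for g in self.groups_ if g != target]
        return _core.group_specific(
            self.core_sets_[target],
            [self.core_sets_[g] for g in others],
            edge_level=edge_level,
        )

    def validate_against(
        self,
        validation: "CoreRegulationAnalysis | Sequence[SampleNetwork]",
        group: str | None = None,
        T_validation: float = 0.4,
        edge_level: bool = False,
    ) -> ValidationResult:
        """Cross-cohort validation of this fit's core set.

        ``validation`` is either another fitted estimator (its sample
        networks for ``group`` are used) or an explicit list of sample
        networks from the validation cohort.
        """
        check_is_fitted(self, "core_sets_")
        core = self.core_set(group)
        if isinstance(validation, CoreRegulationAnalysis):
            check_is_fitted(validation, "sample_networks_")
            g = group if group is not None else validation.groups_[0]
            nets = validation.group_networks(g)
        else:
            nets = list(validation)
        return _core.cross_cohort_validate(
            core, nets, T_validation, edge_level=edge_level
        )

    def group_networks(self, group: str) -> list[SampleNetwork]:
        """The fitted sample networks belonging to one phenotype group."""
        check_is_fitted(self, "sample_networks_")
        if group not in self.groups_:
            raise KeyError(f"unknown group {group!r}")
        return [
            sn for sid, sn in self.sample_networks_.items()
            if self.sample_groups_[sid] == group
        ]

    def t_sweep(
        self, T_grid: Iterable[float], group: str | None = None
    ) -> pd.DataFrame:
        check_is_fitted(self, "frequency_tables_")
        if group is None:
            group = self.core_set().group_label
        return _core.t_sweep(self.frequency_tables_[group], T_grid)
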