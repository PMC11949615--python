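"""The end-to-end functional reconfiguration model.

:class:`FunctionalReconfiguration` is the model object: built from
parcellated time series (or precomputed FCs) plus a covariate table, it holds
the analysis configuration — regularization value, reference segment choice,
predictor order.  ``fit()`` executes the pipeline

    segment -> FC -> regularize -> Riemann-mean reference (rest segments
    only) -> tangent projection -> meta-identifiability -> reconfiguration
    vectors -> OLS models

and returns a :class:`ReconfigurationResults` carrying the reference, the
tangent-FCs, the 25-block meta-identifiability matrix, cross-segment
identification rates, the three transition reconfiguration vectors, and a
fitted regression per transition.

Stability and sensitivity analyses hang off the model object:
``loo_reference_stability`` (rebuild the reference n times leaving one
participant out), ``regularization_sweep`` (re-run the pipeline over a grid
of regularization values), and ``compare_references`` (re-run under
different rest-segment choices for the reference and correlate the
diagonal/off-diagonal structure of the resulting identifiability matrices,
the reference-robustness check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spd
from .connectivity import (
    SEGMENTS,
    BoldTimeSeries,
    FCMatrix,
    SegmentScheme,
    compute_fc,
    default_scheme,
    nominal_scan_volumes,
    split_segments,
    vectorize,
)
from .identifiability import (
    MetaIdentifiabilityMatrix,
    ReconfigurationVector,
    identification_rate,
    meta_identifiability,
    reconfiguration_vector,
)
from .regression import (
    PREDICTORS,
    LooDistribution,
    RegressionResult,
    fit_reconfig_model,
    loo_model_stability,
    prepare_design,
)

__all__ = [
    "TRANSITIONS",
    "REST_SEGMENTS",
    "DEFAULT_LAMBDA_GRID",
    "FunctionalReconfiguration",
    "ReconfigurationResults",
    "SweepResult",
    "ReferenceComparison",
]

#: named rest/task transitions: (from_segment, to_segment)
TRANSITIONS = {
    "engaging": ("R1.2", "SST"),
    "disengaging": ("SST", "R2.1"),
    "within_rest": ("R2.1", "R2.2"),
}

REST_SEGMENTS = ("R1.1", "R1.2", "R2.1", "R2.2")

#: default regularization sweep grid
DEFAULT_LAMBDA_GRID = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.1, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass
class SweepResult:
    """Pipeline outputs across a grid of regularization values."""

    lambdas: list
    pooled_variance: list
    models: dict  # transition -> list[RegressionResult], aligned with lambdas

    def __post_init__(self):
        lam = list(self.lambdas)
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValueError("regularization values must be strictly increasing")
        self.lambdas = lam

    def table(self, transition: str, predictors=None) -> pd.DataFrame:
        """Per-lambda R^2 and per-predictor p values for one transition."""
        rows = []
        for lam, res in zip(self.lambdas, self.models[transition]):
            row = {"lambda": lam, "r_squared": res.r_squared}
            for pred in predictors or res.predictor_order:
                row[f"p_{pred}"] = res.pvalues[pred]
                row[f"coef_{pred}"] = res.params[pred]
            rows.append(row)
        return pd.DataFrame(rows).set_index("lambda")


@dataclass
class ReferenceComparison:
    """Cross-reference correlations of identifiability structure.

    For each pair of reference choices, 5 x 5 tables of Pearson correlations
    between (a) the diagonal (reconfiguration) vectors and (b) the
    off-diagonal entries of corresponding identifiability matrices.
    Within-segment diagonals are identically zero, hence NaN.
    """

    diagonal: dict  # (choiceA, choiceB) -> DataFrame 5x5
    off_diagonal: dict


def _label_ref(segments, lam) -> str:
    return f"riemann[{'+'.join(segments)}]@lam={lam:g}"


class FunctionalReconfiguration:
    """Model of rest/task functional reconfiguration for one cohort.

    Parameters
    ----------
    fcs : dict segment -> list of FCMatrix
        Raw (unregularized) per-segment functional connectomes, one list
        entry per participant in ``subject_order``.
    covariates : DataFrame
        Raw covariate table indexed by subject id (see
        :data:`tanrec.regression.RAW_COVARIATE_COLUMNS`), or a table already
        carrying the seven modeled predictors.
    lam : float
        Diagonal regularization value (default 0.001).
    reference_segments : sequence of segment labels
        Rest segments pooled to build the Riemann-mean reference (default
        R1.1).  Task segments are refused unless ``allow_task_reference``:
        using SST would cancel the very structure being measured.
    predictor_order : sequence
        Order in which predictors enter the additive-R^2 sequence.
    """

    def __init__(
        self,
        fcs: dict,
        covariates: pd.DataFrame,
        subject_order=None,
        lam: float = 0.001,
        reference_segments=("R1.1",),
        predictor_order=PREDICTORS,
        include_diagonal: bool = False,
        allow_task_reference: bool = False,
    ):
        missing = [s for s in SEGMENTS if s not in fcs]
        if missing:
            raise ValueError(f"missing FC segment(s) {missing}")
        if lam <= 0:
            raise ValueError("regularization value must be positive")
        for seg in reference_segments:
            if seg not in SEGMENTS:
                raise ValueError(f"unknown reference segment {seg!r}")
            if seg not in REST_SEGMENTS and not allow_task_reference:
                raise ValueError(
                    f"reference segment {seg!r} is not a resting segment; the "
                    "reference is restricted to rest to preserve task structure "
                    "(pass allow_task_reference=True to override)"
                )
        n = len(fcs[SEGMENTS[0]])
        if any(len(fcs[s]) != n for s in SEGMENTS):
            raise ValueError("segments cover different participant counts")
        if subject_order is None:
            subject_order = [f.subject_id or f"s{i}" for i, f in enumerate(fcs["R1.1"])]
        if len(subject_order) != n:
            raise ValueError("subject_order length mismatch")
        cov = covariates.loc[list(subject_order)]
        self.fcs = fcs
        self.covariates = cov
        self.subject_order = list(subject_order)
        self.lam = float(lam)
        self.reference_segments = tuple(reference_segments)
        self.predictor_order = tuple(predictor_order)
        self.include_diagonal = bool(include_diagonal)
        self.design, self.drinking_variance_explained = prepare_design(cov)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_time_series(
        cls,
        time_series: dict,
        covariates: pd.DataFrame,
        scheme: SegmentScheme | None = None,
        tr_seconds: float = 1.2,
        **kwargs,
    ) -> "FunctionalReconfiguration":
        """Build the model from ``{(subject_id, scan_id): BoldTimeSeries}``.

        Each subject needs both scans; segments are cut with ``scheme``
        (default: the nominal two-scan layout at ``tr_seconds``).
        """
        subjects = sorted({sid for sid, _ in time_series}, key=str)
        ordered = [s for s in covariates.index if s in set(subjects)]
        if set(ordered) != set(subjects):
            raise ValueError("covariate table does not cover all subjects")
        if scheme is None:
            scheme = default_scheme(tr_seconds, *nominal_scan_volumes(tr_seconds))
        fcs = {s: [] for s in SEGMENTS}
        for sid in ordered:
            for scan_id in ("scan1", "scan2"):
                if (sid, scan_id) not in time_series:
                    raise ValueError(f"subject {sid} is missing {scan_id}")
                ts = time_series[(sid, scan_id)]
                for label, sub in split_segments(ts, scheme):
                    fcs[label].append(compute_fc(sub, subject_id=sid, segment_label=label))
        return cls(fcs, covariates, subject_order=ordered, **kwargs)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "FunctionalReconfiguration":
        """Build the model from a synthetic :class:`~tanrec.synthetic.Cohort`."""
        return cls.from_time_series(
            cohort.time_series,
            cohort.covariates,
            tr_seconds=cohort.config.tr_seconds,
            **kwargs,
        )

    # -- pipeline stages ----------------------------------------------------

    def _regularized(self, lam: float) -> dict:
        return {
            seg: [spd.regularize(f, lam, label=f.label) for f in self.fcs[seg]]
            for seg in SEGMENTS
        }

    def _reference(self, reg: dict, reference_segments, exclude_subject=None):
        pool = []
        for seg in reference_segments:
            for i, m in enumerate(reg[seg]):
                if exclude_subject is not None and self.subject_order[i] == exclude_subject:
                    continue
                pool.append(m)
        label = _label_ref(reference_segments, self.lam)
        if exclude_subject is not None:
            label += f"-loo:{exclude_subject}"
        return spd.riemann_mean(pool, label=label)

    def _project(self, reg: dict, reference) -> dict:
        return {
            seg: spd.tangent_project_many(reg[seg], reference, reference_id=reference.label)
            for seg in SEGMENTS
        }

    def _transition_vectors(self, tfcs: dict) -> dict:
        from .identifiability import identifiability_matrix

        out = {}
        for name, (a, b) in TRANSITIONS.items():
            idm = identifiability_matrix(
                tfcs[a],
                tfcs[b],
                segment_pair=(a, b),
                subject_order=self.subject_order,
                include_diagonal=self.include_diagonal,
            )
            out[name] = reconfiguration_vector(idm)
        return out

    # -- main fit -----------------------------------------------------------

    def fit(self, compute_manifold_rates: bool = False) -> "ReconfigurationResults":
        """Run the full pipeline and fit the three transition models."""
        reg = self._regularized(self.lam)
        reference = self._reference(reg, self.reference_segments)
        tfcs = self._project(reg, reference)
        meta = meta_identifiability(
            tfcs, subject_order=self.subject_order, include_diagonal=self.include_diagonal
        )
        rates = self._rates(meta)
        manifold_rates = None
        if compute_manifold_rates:
            manifold_meta = meta_identifiability(
                {s: [m.values for m in reg[s]] for s in SEGMENTS},
                subject_order=self.subject_order,
                include_diagonal=self.include_diagonal,
            )
            manifold_rates = self._rates(manifold_meta)
        vectors = {
            name: reconfiguration_vector(meta.block(a, b))
            for name, (a, b) in TRANSITIONS.items()
        }
        models = {
            name: fit_reconfig_model(vec.values, self.design, self.predictor_order)
            for name, vec in vectors.items()
        }
        return ReconfigurationResults(
            model=self,
            reference=reference,
            tangent_fcs=tfcs,
            meta=meta,
            identification_rates=rates,
            manifold_identification_rates=manifold_rates,
            reconfiguration=vectors,
            models=models,
        )

    @staticmethod
    def _rates(meta: MetaIdentifiabilityMatrix) -> pd.DataFrame:
        rates = pd.DataFrame(index=list(SEGMENTS), columns=list(SEGMENTS), dtype=float)
        for a in SEGMENTS:
            for b in SEGMENTS:
                if a != b:
                    rates.loc[a, b] = identification_rate(meta.block(a, b))
        return rates

    # -- stability / sensitivity -------------------------------------------

    def loo_model_stability(self, transition: str = "engaging") -> LooDistribution:
        """Model-level leave-one-out: refit excluding each participant."""
        results = self.fit()
        vec = results.reconfiguration[transition]
        return loo_model_stability(vec.values, self.design, self.predictor_order)

    def loo_reference_stability(self, transition: str = "engaging") -> LooDistribution:
        """Reference-level leave-one-out.

        For each held-out participant, the Riemann-mean reference is rebuilt
        on the remaining n-1 reference-segment FCs, *all* n participants are
        re-projected, the transition's reconfiguration vector is recomputed
        and the full-n model refitted.  Returns the n coefficient vectors.
        """
        reg = self._regularized(self.lam)
        a, b = TRANSITIONS[transition]
        rows = []
        for sid in self.subject_order:
            ref = self._reference(reg, self.reference_segments, exclude_subject=sid)
            tfcs = {
                seg: spd.tangent_project_many(reg[seg], ref, reference_id=ref.label)
                for seg in (a, b)
            }
            from .identifiability import identifiability_matrix

            idm = identifiability_matrix(
                tfcs[a], tfcs[b], segment_pair=(a, b),
                subject_order=self.subject_order,
                include_diagonal=self.include_diagonal,
            )
            vec = reconfiguration_vector(idm)
            res = fit_reconfig_model(vec.values, self.design, self.predictor_order)
            rows.append(res.params)
        coef = pd.DataFrame(rows, index=self.subject_order)
        return LooDistribution(
            coefficients=coef, mode="reference_loo",
            predictor_order=list(self.predictor_order),
        )

    def regularization_sweep(
        self, lambdas=DEFAULT_LAMBDA_GRID, transitions=("engaging", "disengaging")
    ) -> SweepResult:
        """Re-run the pipeline for each regularization value.

        For each lambda the FCs are re-regularized, the reference and
        tangent-FCs recomputed, and each requested transition's model
        refitted.  ``pooled_variance`` is the variance of all vectorized
        tangent-FC elements pooled over subjects and segments — the
        shrinking effect of regularization makes it decrease with lambda.
        """
        lams = [float(x) for x in lambdas]
        if any(x <= 0 for x in lams):
            raise ValueError("regularization values must be positive")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("regularization values must be strictly increasing")
        pooled, models = [], {t: [] for t in transitions}
        for lam in lams:
            reg = self._regularized(lam)
            ref = spd.riemann_mean(
                [m for seg in self.reference_segments for m in reg[seg]],
                label=_label_ref(self.reference_segments, lam),
            )
            tfcs = self._project(reg, ref)
            elements = np.concatenate(
                [
                    vectorize(t, include_diagonal=self.include_diagonal)
                    for seg in SEGMENTS
                    for t in tfcs[seg]
                ]
            )
            pooled.append(float(elements.var(ddof=1)))
            vectors = self._transition_vectors(tfcs)
            for t in transitions:
                models[t].append(
                    fit_reconfig_model(vectors[t].values, self.design, self.predictor_order)
                )
        return SweepResult(lambdas=lams, pooled_variance=pooled, models=models)

    def compare_references(self, ref_choices=(("R1.1",), ("R2.2",), ("R1.1", "R2.2"))):
        """Correlate identifiability structure across reference choices.

        Mirrors the reference-robustness analysis: for every pair of
        reference choices, correlate per segment-pair block (a) the diagonal
        reconfiguration vectors and (b) the off-diagonal entries.
        """
        choices = [tuple(c) for c in ref_choices]
        if len(choices) < 2:
            raise ValueError("need at least two reference choices")
        reg = self._regularized(self.lam)
        metas = {}
        for choice in choices:
            ref = self._reference(reg, choice)
            tfcs = self._project(reg, ref)
            metas[choice] = meta_identifiability(
                tfcs, subject_order=self.subject_order,
                include_diagonal=self.include_diagonal,
            )
        diagonal, off_diagonal = {}, {}
        for i, ca in enumerate(choices):
            for cb in choices[i + 1:]:
                dtab = pd.DataFrame(index=list(SEGMENTS), columns=list(SEGMENTS), dtype=float)
                otab = pd.DataFrame(index=list(SEGMENTS), columns=list(SEGMENTS), dtype=float)
                for a in SEGMENTS:
                    for b in SEGMENTS:
                        va, vb = metas[ca].block(a, b), metas[cb].block(a, b)
                        if a != b:
                            dtab.loc[a, b] = float(
                                np.corrcoef(np.diag(va.values), np.diag(vb.values))[0, 1]
                            )
                        otab.loc[a, b] = float(
                            np.corrcoef(va.off_diagonal(), vb.off_diagonal())[0, 1]
                        )
                diagonal[(ca, cb)] = dtab
                off_diagonal[(ca, cb)] = otab
        return ReferenceComparison(diagonal=diagonal, off_diagonal=off_diagonal)


@dataclass
class ReconfigurationResults:
    """Fitted pipeline outputs for one cohort and configuration."""

    model: FunctionalReconfiguration
    reference: spd.SPDMatrix
    tangent_fcs: dict
    meta: MetaIdentifiabilityMatrix
    identification_rates: pd.DataFrame
    manifold_identification_rates: pd.DataFrame | None
    reconfiguration: dict
    models: dict

    @property
    def subject_order(self) -> list:
        return self.model.subject_order

    def regression(self, transition: str) -> RegressionResult:
        return self.models[transition]

    def summary(self) -> str:
        m = self.model
        lines = [
            "Functional reconfiguration pipeline",
            f"  participants: {len(m.subject_order)}, regions: "
            f"{self.reference.p}, lambda: {m.lam:g}, reference: "
            f"{'+'.join(m.reference_segments)}",
            "",
            "Cross-segment identification rates (%):",
            self.identification_rates.to_string(float_format=lambda v: f"{v:6.1f}"),
            "",
        ]
        for name, vec in self.reconfiguration.items():
            lines.append(
                f"{name:<12} mean reconfiguration {vec.values.mean():.4f} "
                f"(sd {vec.values.std(ddof=1):.4f})"
            )
        for name, res in self.models.items():
            lines += ["", f"--- {name} model ---", res.summary()]
        return "\n".join(lines)
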