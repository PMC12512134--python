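"""Model/Results facade over the federated pipeline.

``FREDA`` is constructed from data (per-client source datasets plus the
unlabeled, group-tagged target dataset); ``fit()`` executes the four-phase
protocol and returns a :class:`FREDAResults` carrying the per-group adaptive
models, their penalty weights and regularization strengths, the protocol
transcript with its privacy audit, and accuracy diagnostics when held-out
target labels are supplied.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DomainDataset, horvath_inverse
from .exceptions import ConfigurationError
from .pipeline import RunConfig, RunReport, run_centralized_wenda, run_freda
from .wen import predict as wen_predict

__all__ = ["FREDA", "FREDAResults"]


class FREDA:
    """Federated unsupervised domain adaptation for regression.

    Parameters
    ----------
    sources : sequence of DomainDataset
        Labeled per-client source datasets (one entry per source party).
    target : DomainDataset
        Unlabeled target dataset with per-sample group (tissue) tags.
    similarity : mapping group -> float, optional
        Domain-similarity scores used by the prior-knowledge lambda path.
    config : RunConfig, optional
        Protocol and training settings; defaults follow the method's
        standard schedule (100 global rounds x 20 local epochs, alpha=0.8,
        k=3).
    """

    def __init__(
        self,
        sources: Sequence[DomainDataset],
        target: DomainDataset,
        similarity: Mapping[str, float] | None = None,
        config: RunConfig | None = None,
    ):
        self.sources = list(sources)
        self.target = target
        self.similarity = dict(similarity) if similarity is not None else None
        self.config = config or RunConfig()

    @classmethod
    def from_dataframes(
        cls,
        source_frames: Sequence[pd.DataFrame],
        target_frame: pd.DataFrame,
        label_col: str = "__label__",
        group_col: str = "__group__",
        similarity: Mapping[str, float] | None = None,
        config: RunConfig | None = None,
    ) -> "FREDA":
        """Build the model from pandas DataFrames (one per source client)."""
        sources = []
        for i, df in enumerate(source_frames):
            if label_col not in df:
                raise ConfigurationError(f"source frame {i} lacks label column {label_col!r}")
            df = df.copy()
            y = df.pop(label_col).to_numpy(dtype=float)
            df.pop(group_col, None)
            sources.append(
                DomainDataset(df.to_numpy(dtype=float), y, None, domain_id=f"source{i}",
                              feature_names=tuple(df.columns))
            )
        tf = target_frame.copy()
        if group_col not in tf:
            raise ConfigurationError(f"target frame lacks group column {group_col!r}")
        groups = tf.pop(group_col).to_numpy()
        tf.pop(label_col, None)
        target = DomainDataset(tf.to_numpy(dtype=float), None, groups, domain_id="target",
                               feature_names=tuple(tf.columns))
        return cls(sources, target, similarity=similarity, config=config)

    def fit(
        self,
        ground_truth: Mapping | None = None,
        federated: bool = True,
        **config_overrides,
    ) -> "FREDAResults":
        """Run the pipeline and return the fitted results.

        ``ground_truth`` (when available, e.g. for synthetic data) supplies
        the labels of the lambda-fitting target groups and enables MAE
        diagnostics; ``federated=False`` runs the pooled non-private
        reference path instead.
        """
        config = (
            replace(self.config, **config_overrides) if config_overrides else self.config
        )
        runner = run_freda if federated else run_centralized_wenda
        report = runner(
            self.sources,
            self.target,
            config=config,
            similarity=self.similarity,
            ground_truth=ground_truth,
        )
        return FREDAResults(self, report)


class FREDAResults:
    """Fitted per-group weighted-elastic-net models plus diagnostics."""

    def __init__(self, model: FREDA, report: RunReport):
        self.model = model
        self.report = report

    # -- convenient accessors -------------------------------------------------
    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.report.models))

    @property
    def params(self) -> pd.DataFrame:
        """Coefficients, one column per target group."""
        names = self.model.target.feature_names or tuple(
            f"f{j}" for j in range(self.model.target.p)
        )
        df = pd.DataFrame(
            {g: self.report.models[g].beta for g in self.groups}, index=list(names)
        )
        df.loc["(intercept)"] = [self.report.models[g].intercept for g in self.groups]
        return df

    @property
    def lambdas(self) -> dict[str, float]:
        return dict(self.report.lambdas)

    @property
    def feature_weights(self) -> pd.DataFrame:
        names = self.model.target.feature_names or tuple(
            f"f{j}" for j in range(self.model.target.p)
        )
        modeled = [names[r.feature] for r in self.report.feature_results]
        return pd.DataFrame(
            {g: self.report.weights[g].values for g in self.groups}, index=modeled
        )

    @property
    def predicted_ages(self) -> np.ndarray:
        return self.report.predicted_ages

    def predict(self, X: np.ndarray, group: str) -> np.ndarray:
        """Predict (transformed-age scale) with the given group's model."""
        if group not in self.report.models:
            raise ConfigurationError(f"no model for group {group!r}")
        return wen_predict(self.report.models[group], np.asarray(X, dtype=float))

    def predict_age(self, X: np.ndarray, group: str) -> np.ndarray:
        lo = np.log(1.0 / (self.report.config.adult_age + 1.0))
        t = np.clip(self.predict(X, group), lo, None)
        return horvath_inverse(t, self.report.config.adult_age)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        r = self.report
        lines = []
        lines.append("FREDA: federated weighted elastic net domain adaptation")
        lines.append("=" * 60)
        lines.append(f"source clients:       {len(self.model.sources)}")
        lines.append(f"target samples:       {self.model.target.n}")
        lines.append(f"features modeled:     {len(r.feature_results)} / {self.model.target.p}")
        lines.append(f"alpha / k:            {r.config.alpha} / {r.config.k}")
        lines.append(f"lambda mode:          {r.config.lambda_mode}")
        if r.fit_groups:
            lines.append(f"lambda fit groups:    {', '.join(r.fit_groups)}")
        if r.lambda_line is not None:
            lines.append(
                "similarity->lambda:   log10(lambda) = "
                f"{r.lambda_line.slope:+.3f} * s {r.lambda_line.intercept:+.3f}"
            )
        lines.append("-" * 60)
        lines.append(f"{'group':<10}{'lambda':>12}{'mean weight':>14}{'MAE (years)':>14}")
        for g in self.groups:
            mae = "" if r.mae_per_group is None else f"{r.mae_per_group.get(g, float('nan')):.3f}"
            lines.append(
                f"{g:<10}{r.lambdas[g]:>12.4g}"
                f"{float(np.mean(r.weights[g].values)):>14.4f}{mae:>14}"
            )
        lines.append("-" * 60)
        if r.mae_eval is not None:
            lines.append(f"MAE on held-out groups:  {r.mae_eval:.3f} years")
        if r.mae_overall is not None:
            lines.append(f"MAE on all target rows:  {r.mae_overall:.3f} years")
        if r.audit is not None:
            lines.append(
                f"privacy audit:           {'PASS' if r.audit.passed else 'FAIL'}"
                f" ({r.audit.n_messages} messages)"
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Serialize models, weights, lambdas, predictions and transcript."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        r = self.report
        models_json = {
            g: {
                "beta": m.beta.tolist(),
                "intercept": m.intercept,
                "lambda": r.lambdas[g],
                "alpha": m.alpha,
                "k": r.config.k,
            }
            for g, m in r.models.items()
        }
        (out / "models.json").write_text(json.dumps(models_json, indent=1))
        names = self.model.target.feature_names or tuple(
            f"f{j}" for j in range(self.model.target.p)
        )
        rows = []
        for g in self.groups:
            for i, res in enumerate(r.feature_results):
                rows.append(
                    {
                        "group": g,
                        "feature": names[res.feature],
                        "confidence": r.confidences[g].values[i],
                        "weight": r.weights[g].values[i],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "feature_weights.csv", index=False)
        pd.DataFrame(
            {
                "group": self.model.target.groups.astype(str),
                "prediction_transformed": r.predictions,
                "predicted_age": r.predicted_ages,
            }
        ).to_csv(out / "predictions.csv", index=False)
        lam_report = {
            "lambdas": r.lambdas,
            "fit_groups": list(r.fit_groups),
            "eval_groups": list(r.eval_groups),
        }
        if r.lambda_line is not None:
            lam_report["similarity_model"] = {
                "slope": r.lambda_line.slope,
                "intercept": r.lambda_line.intercept,
                "scale": r.lambda_line.scale,
            }
        (out / "lambda_report.json").write_text(json.dumps(lam_report, indent=1))
        if r.transcript is not None:
            r.transcript.to_jsonl(out / "transcript.jsonl")
        if r.audit is not None:
            (out / "audit.json").write_text(
                json.dumps(
                    {
                        "passed": r.audit.passed,
                        "n_messages": r.audit.n_messages,
                        "violations": r.audit.violations,
                    },
                    indent=1,
                )
            )
        with open(out / "feature_models.jsonl", "w") as fh:
            for res in r.feature_results:
                fh.write(json.dumps(res.to_record()) + "\n")
        (out / "summary.txt").write_text(self.summary() + "\n")
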