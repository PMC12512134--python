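"""Four-phase pipeline over simulated parties.

Phase 1 — feature models: per-feature GPR hyper-parameters are optimized
locally and securely averaged; Gram matrices are assembled by the aggregator
from randomized encodings; the masked mean protocol and the variance
diagonal deliver each feature's predictive distribution to the target.

Phase 2 — weights: the target converts predictive distributions into
per-group confidences and penalty weights, relayed to the source clients via
the aggregator.

Phase 3 — lambda: weighted elastic nets are trained federatively over a
lambda grid for the labeled target groups; a log10(lambda)-on-similarity
line predicts lambda for the held-out groups (or a similarity-free source
CV fallback).

Phase 4 — final models: one federated weighted elastic net per target group,
broadcast to the target for inference.

A parallel non-federated path (:func:`run_centralized_wenda`) computes the
same mathematics on pooled data and serves as the equivalence oracle.
"""

from __future__ import annotations

import hashlib
import itertools
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .confidence import (
    ConfidenceVector,
    FeatureWeightVector,
    aggregate_confidence,
    compute_feature_weights,
    confidence_score,
)
from .datasets import DomainDataset, horvath_inverse
from .exceptions import ConfigurationError
from .federation import AGGREGATOR, TARGET, AuditReport, ProtocolTranscript, audit_transcript, payload_digest
from .gpr import (
    FeatureModelResult,
    GPRHyperparams,
    assemble_kernel_matrices,
    centralized_gpr_oracle,
    optimize_local_hyperparams,
    predicted_mean_protocol,
    predicted_variance,
)
from .lambda_select import (
    LambdaSimilarityModel,
    cv_select_lambda,
    default_lambda_grid,
    fit_similarity_lambda_model,
    predict_lambda,
    select_best_lambda,
)
from .masking import encode_matrix, generate_shared_mask, gram_from_encoded, make_row_mask
from .secure_agg import (
    FixedPointCodec,
    derive_zero_sum_masks,
    pairwise_seeds_from,
    secure_sum,
)
from .wen import TrainingSchedule, WENModel, predict, train_federated_wen

__all__ = [
    "RunConfig",
    "RunReport",
    "run_freda",
    "run_centralized_wenda",
    "run_feature_models",
    "compute_group_weights",
]


@dataclass
class RunConfig:
    """Everything that, together with the input files, determines a run."""

    seed: int = 0
    n_sources: int = 4
    proportions: Sequence[float] | str = "uniform"
    k: float = 3.0
    alpha: float = 0.8
    lambda_mode: str = "prior-knowledge"  # or "cv"
    lambda_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_lambda_grid())
    )
    fit_groups: tuple[str, ...] | None = None
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    d_extra: int = 10
    frac_bits: int = 32
    feature_subset: tuple[int, ...] | None = None
    include_noise_in_confidence: bool = True
    hyper_override: tuple[float, float] | None = None
    adult_age: float = 20.0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        self.lambda_grid = tuple(float(l) for l in self.lambda_grid)
        if self.fit_groups is not None:
            self.fit_groups = tuple(str(g) for g in self.fit_groups)
        if self.feature_subset is not None:
            self.feature_subset = tuple(int(f) for f in self.feature_subset)

    def validate(self) -> None:
        if self.n_sources < 1:
            raise ConfigurationError("n_sources must be >= 1")
        if self.k <= 0:
            raise ConfigurationError("k must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.lambda_mode not in ("prior-knowledge", "cv"):
            raise ConfigurationError(f"unknown lambda_mode {self.lambda_mode!r}")
        if not self.lambda_grid or any(l <= 0 for l in self.lambda_grid):
            raise ConfigurationError("lambda grid must be nonempty and positive")
        if self.d_extra < 1:
            raise ConfigurationError("d_extra must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "schedule" in d and isinstance(d["schedule"], Mapping):
            d["schedule"] = TrainingSchedule(**d["schedule"])
        for key in ("lambda_grid", "fit_groups", "feature_subset", "hyper_override"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["schedule"] = dict(vars(self.schedule))
        d["lambda_grid"] = list(self.lambda_grid)
        for key in ("fit_groups", "feature_subset", "hyper_override"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


@dataclass
class RunReport:
    """Everything a run produced, plus the transcript and its audit."""

    config: RunConfig
    feature_results: list[FeatureModelResult]
    confidences: dict[str, ConfidenceVector]
    weights: dict[str, FeatureWeightVector]
    lambdas: dict[str, float]
    lambda_line: LambdaSimilarityModel | None
    fit_groups: tuple[str, ...]
    eval_groups: tuple[str, ...]
    models: dict[str, WENModel]
    predictions: np.ndarray  # transformed-age space, aligned with target rows
    predicted_ages: np.ndarray
    mae_per_group: dict[str, float] | None
    mae_eval: float | None
    mae_overall: float | None
    transcript: ProtocolTranscript | None
    audit: AuditReport | None
    timings: dict[str, float] = field(default_factory=dict)

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.predictions).tobytes())
        for g in sorted(self.models):
            h.update(np.ascontiguousarray(self.models[g].beta).tobytes())
            h.update(np.float64(self.models[g].intercept).tobytes())
            h.update(np.float64(self.lambdas[g]).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# helpers


def _check_inputs(sources: Sequence[DomainDataset], target: DomainDataset) -> None:
    if not sources:
        raise ConfigurationError("need at least one source dataset")
    P = target.p
    for s in sources:
        if s.p != P:
            raise ConfigurationError("all domains must share the feature count")
        if s.y is None:
            raise ConfigurationError(f"source {s.domain_id!r} is unlabeled")
        if s.feature_names and target.feature_names and s.feature_names != target.feature_names:
            raise ConfigurationError("feature order differs between domains")
    if target.groups is None:
        raise ConfigurationError("target dataset must carry group tags")


def _collect_private_digests(sources, target, bundle_seed) -> set[str]:
    digests = set()
    for s in sources:
        digests.add(payload_digest(s.X))
        digests.add(payload_digest(s.y))
        for f in range(s.p):
            digests.add(payload_digest(np.ascontiguousarray(s.X[:, f])))
    digests.add(payload_digest(target.X))
    for f in range(target.p):
        digests.add(payload_digest(np.ascontiguousarray(target.X[:, f])))
    digests.add(payload_digest(int(bundle_seed)))
    return digests


def _recorded_secure_sum(values, codec, masks, transcript, round_id):
    headroom = max(3, int(np.ceil(np.log2(max(len(values), 2)))) + 1)
    with np.errstate(over="ignore"):
        for p in sorted(values):
            share = codec.encode(values[p], headroom=headroom) + masks[p]
            transcript.record(round_id, p, AGGREGATOR, "secure-sum-share", share)
    return secure_sum(values, codec, masks)


def _drop_col(X: np.ndarray, f: int) -> np.ndarray:
    return np.ascontiguousarray(np.delete(X, f, axis=1))


# ---------------------------------------------------------------------------
# Phase 1


def _phase1_federated(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: RunConfig,
    transcript: ProtocolTranscript,
    rounds: itertools.count,
) -> list[FeatureModelResult]:
    src_ids = [f"s{i:02d}" for i in range(len(sources))]
    data = dict(zip(src_ids, sources))
    P = target.p
    subset = list(config.feature_subset) if config.feature_subset else list(range(P))

    # Keying material shared by the data-holding parties only.
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5EED])
    bundle_seed, agg_seed, pair_master = (int(x) for x in ss.generate_state(3))
    for p in src_ids[1:] + [TARGET]:
        transcript.record(0, src_ids[0], p, "mask-seed", int(bundle_seed))
    pair_seeds = pairwise_seeds_from(pair_master, src_ids)
    codec = FixedPointCodec(frac_bits=config.frac_bits)

    d = (P - 1) + config.d_extra
    bundle = generate_shared_mask(bundle_seed, P - 1, d, src_ids + [TARGET])

    sizes = [data[sid].n for sid in src_ids]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    slices = {sid: slice(int(offsets[i]), int(offsets[i + 1])) for i, sid in enumerate(src_ids)}
    n_S = int(offsets[-1])

    results = []
    for f in subset:
        rid = next(rounds)
        # --- federated hyper-parameter optimization
        if config.hyper_override is not None:
            hyper = GPRHyperparams(*config.hyper_override)
        else:
            contrib = {}
            for sid in src_ids:
                ds = data[sid]
                local = optimize_local_hyperparams(_drop_col(ds.X, f), ds.X[:, f])
                contrib[sid] = np.array([local.sigma_k2, local.sigma_eps2])
            if len(src_ids) == 1:
                total = contrib[src_ids[0]]
            else:
                masks = derive_zero_sum_masks(src_ids, (2,), rid, pair_seeds)
                total = _recorded_secure_sum(contrib, codec, masks, transcript, rid)
            mean = total / len(src_ids)
            hyper = GPRHyperparams(float(mean[0]), float(mean[1]))
        for sid in src_ids:
            transcript.record(rid, AGGREGATOR, sid, "global-hyperparams", np.array([hyper.sigma_k2, hyper.sigma_eps2]))

        # --- randomized-encoding Gram assembly at the aggregator
        enc = {}
        for sid in src_ids:
            enc[sid] = encode_matrix(_drop_col(data[sid].X, f), bundle, sid)
            transcript.record(rid, sid, AGGREGATOR, "encoded-matrix", enc[sid].values)
        enc_t = encode_matrix(_drop_col(target.X, f), bundle, TARGET)
        transcript.record(rid, TARGET, AGGREGATOR, "encoded-matrix", enc_t.values)

        gram_ss = np.empty((n_S, n_S))
        for p in src_ids:
            for q in src_ids:
                gram_ss[slices[p], slices[q]] = gram_from_encoded(enc[p], enc[q])
        gram_ss = 0.5 * (gram_ss + gram_ss.T)  # symmetrize float noise from masked blocks
        gram_ts = np.hstack([gram_from_encoded(enc_t, enc[p]) for p in src_ids])
        gram_tt = gram_from_encoded(enc_t, enc_t)

        K, K_star, K_star_star = assemble_kernel_matrices(gram_ss, gram_ts, gram_tt, hyper, n_S)

        # --- masked predicted-mean protocol + variance diagonal
        row_mask = make_row_mask(target.n, seed=(agg_seed + 7919 * f) & 0x7FFFFFFF)
        transcript.record(rid, AGGREGATOR, TARGET, "row-mask-inverse", row_mask.C_inv)
        feature_columns = {sid: np.ascontiguousarray(data[sid].X[:, f]) for sid in src_ids}
        mean = predicted_mean_protocol(
            K_star, K, feature_columns, row_mask, slices, recorder=transcript.record, round_id=rid
        )
        var = predicted_variance(K_star_star, K_star, K)
        transcript.record(rid, AGGREGATOR, TARGET, "pred-variance", var)
        results.append(FeatureModelResult(feature=f, hyper=hyper, mean=mean, variance=var))
    return results


def _phase1_centralized(
    pooled: DomainDataset, target: DomainDataset, config: RunConfig
) -> list[FeatureModelResult]:
    subset = list(config.feature_subset) if config.feature_subset else list(range(target.p))
    results = []
    for f in subset:
        X_nf, x_f = _drop_col(pooled.X, f), pooled.X[:, f]
        if config.hyper_override is not None:
            hyper = GPRHyperparams(*config.hyper_override)
        else:
            hyper = optimize_local_hyperparams(X_nf, x_f)
        mean, var = centralized_gpr_oracle(X_nf, x_f, _drop_col(target.X, f), hyper)
        results.append(FeatureModelResult(feature=f, hyper=hyper, mean=mean, variance=var))
    return results


def run_feature_models(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: RunConfig | None = None,
    transcript: ProtocolTranscript | None = None,
) -> list[FeatureModelResult]:
    """Phase 1 only: federated per-feature predictive distributions."""
    config = config or RunConfig()
    config.validate()
    _check_inputs(sources, target)
    transcript = transcript if transcript is not None else ProtocolTranscript()
    return _phase1_federated(sources, target, config, transcript, itertools.count(1))


def compute_group_weights(
    feature_results: Sequence[FeatureModelResult],
    target: DomainDataset,
    config: RunConfig | None = None,
):
    """Phase 2 only: per-group confidences and penalty weights."""
    return _phase2_weights(feature_results, target, config or RunConfig())


# ---------------------------------------------------------------------------
# Phase 2


def _phase2_weights(
    feature_results: Sequence[FeatureModelResult],
    target: DomainDataset,
    config: RunConfig,
) -> tuple[dict[str, ConfidenceVector], dict[str, FeatureWeightVector]]:
    groups = [str(g) for g in np.unique(target.groups)]
    n_feat = len(feature_results)
    conf_matrix = {g: np.empty(n_feat) for g in groups}
    labels = target.groups.astype(str)
    for idx, res in enumerate(feature_results):
        sigma2 = res.variance
        if config.include_noise_in_confidence:
            sigma2 = sigma2 + res.hyper.sigma_eps2
        per_sample = confidence_score(target.X[:, res.feature], res.mean, np.sqrt(sigma2))
        per_group = aggregate_confidence(per_sample, labels)
        for g in groups:
            conf_matrix[g][idx] = per_group[g]
    confidences = {g: ConfidenceVector(group=g, values=conf_matrix[g]) for g in groups}
    weights = {g: compute_feature_weights(confidences[g], config.k) for g in groups}
    return confidences, weights


# ---------------------------------------------------------------------------
# Phases 3 and 4 (shared between federated and centralized paths)


def _phase34(
    train_fn,
    weights: Mapping[str, FeatureWeightVector],
    target: DomainDataset,
    config: RunConfig,
    similarity: Mapping[str, float] | None,
    fit_labels: Mapping[str, np.ndarray] | None,
    cv_fn=None,
):
    groups = sorted(weights)
    labels = target.groups.astype(str)
    grid = sorted(config.lambda_grid)
    lambdas: dict[str, float] = {}
    line = None

    if config.lambda_mode == "cv":
        if cv_fn is None:
            raise ConfigurationError("cv lambda mode needs a source-side CV routine")
        fit_groups: tuple[str, ...] = ()
        for g in groups:
            lambdas[g] = cv_fn(weights[g].values)
    else:
        fit_groups = tuple(str(g) for g in (config.fit_groups or (groups[0], groups[-1])))
        for g in fit_groups:
            if g not in groups:
                raise ConfigurationError(f"fit group {g!r} not present in target")
        if similarity is None:
            raise ConfigurationError("prior-knowledge lambda mode needs similarity scores")
        if fit_labels is None or any(g not in fit_labels for g in fit_groups):
            raise ConfigurationError("prior-knowledge lambda mode needs labels for fit groups")
        points = []
        for g in fit_groups:
            models = {lam: train_fn(weights[g].values, lam) for lam in grid}
            rows = labels == g
            lam_best = select_best_lambda(
                models, target.X[rows], np.asarray(fit_labels[g], dtype=float), config.adult_age
            )
            lambdas[g] = lam_best
            points.append((float(similarity[g]), lam_best))
        eval_gs = [g for g in groups if g not in fit_groups]
        if eval_gs:
            line = fit_similarity_lambda_model(points)
            for g in eval_gs:
                lambdas[g] = predict_lambda(
                    line, float(similarity[g]), grid_range=(grid[0], grid[-1])
                )

    models = {g: train_fn(weights[g].values, lambdas[g]) for g in groups}
    predictions = np.empty(target.n)
    for g in groups:
        rows = labels == g
        predictions[rows] = predict(models[g], target.X[rows])
    eval_groups = tuple(g for g in groups if g not in fit_groups)
    return lambdas, line, fit_groups, eval_groups, models, predictions


def _evaluate(predictions, target, y_true, fit_groups, config):
    if y_true is None:
        return None, None, None
    lo = np.log(1.0 / (config.adult_age + 1.0))
    ages_pred = horvath_inverse(np.clip(predictions, lo, None), config.adult_age)
    ages_true = horvath_inverse(np.asarray(y_true, dtype=float), config.adult_age)
    labels = target.groups.astype(str)
    abs_err = np.abs(ages_pred - ages_true)
    mae_per_group = {g: float(abs_err[labels == g].mean()) for g in np.unique(labels)}
    eval_mask = ~np.isin(labels, list(fit_groups))
    mae_eval = float(abs_err[eval_mask].mean()) if eval_mask.any() else None
    return mae_per_group, mae_eval, float(abs_err.mean())


def _fit_labels_from_ground_truth(ground_truth, target, fit_groups):
    if ground_truth is None or "y_target" not in ground_truth:
        return None
    labels = target.groups.astype(str)
    y = np.asarray(ground_truth["y_target"], dtype=float)
    return {g: y[labels == g] for g in fit_groups}


# ---------------------------------------------------------------------------
# entry points


def run_freda(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: RunConfig | None = None,
    similarity: Mapping[str, float] | None = None,
    ground_truth: Mapping | None = None,
) -> RunReport:
    """Run the full federated pipeline over simulated parties.

    ``similarity`` maps target group -> similarity score (defaults to the
    ground-truth record's table when present).  Ground-truth target labels
    are consulted only for the labeled lambda-fitting groups and, at the very
    end, for MAE reporting.
    """
    config = config or RunConfig()
    config.validate()
    _check_inputs(sources, target)
    transcript = ProtocolTranscript()
    rounds = itertools.count(1)
    timings: dict[str, float] = {}

    if similarity is None and ground_truth is not None:
        similarity = ground_truth.get("similarity")

    t0 = time.perf_counter()
    feature_results = _phase1_federated(sources, target, config, transcript, rounds)
    timings["phase1_feature_models"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    confidences, weights = _phase2_weights(feature_results, target, config)
    src_ids = [f"s{i:02d}" for i in range(len(sources))]
    for g, w in sorted(weights.items()):
        rid = next(rounds)
        transcript.record(rid, TARGET, AGGREGATOR, "feature-weights", w.values)
        for sid in src_ids:
            transcript.record(rid, AGGREGATOR, sid, "feature-weights", w.values)
    timings["phase2_weights"] = time.perf_counter() - t0

    clients = {sid: (s.X, s.y) for sid, s in zip(src_ids, sources)}
    pair_master = int(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5EED]).generate_state(3)[2]
    )
    pair_seeds = pairwise_seeds_from(pair_master, src_ids) if len(src_ids) > 1 else None
    codec = FixedPointCodec(frac_bits=config.frac_bits)
    round_base = itertools.count(10_000)

    def train_fn(weight_values: np.ndarray, lam: float) -> WENModel:
        return train_federated_wen(
            clients,
            weight_values,
            lam,
            config.alpha,
            config.schedule,
            codec=codec,
            pairwise_seeds=pair_seeds,
            recorder=transcript.record,
            round_offset=next(round_base) * config.schedule.global_rounds,
        )

    def cv_fn(weight_values: np.ndarray) -> float:
        return cv_select_lambda(
            clients,
            weight_values,
            config.lambda_grid,
            folds=config.cv_folds,
            alpha=config.alpha,
            schedule=config.schedule,
            adult_age=config.adult_age,
            seed=config.seed,
            pairwise_seeds=pair_seeds,
        )

    groups = sorted(str(g) for g in np.unique(target.groups))
    fit_groups_cfg = tuple(
        str(g) for g in (config.fit_groups or ((groups[0], groups[-1]) if config.lambda_mode == "prior-knowledge" else ()))
    )
    fit_labels = _fit_labels_from_ground_truth(ground_truth, target, fit_groups_cfg)

    t0 = time.perf_counter()
    lambdas, line, fit_groups, eval_groups, models, predictions = _phase34(
        train_fn, weights, target, config, similarity, fit_labels, cv_fn=cv_fn
    )
    timings["phase3_phase4_training"] = time.perf_counter() - t0

    y_true = None if ground_truth is None else ground_truth.get("y_target")
    mae_per_group, mae_eval, mae_overall = _evaluate(
        predictions, target, y_true, fit_groups, config
    )

    bundle_seed = int(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5EED]).generate_state(3)[0]
    )
    private = _collect_private_digests(sources, target, bundle_seed)
    audit = audit_transcript(transcript, private)

    lo = np.log(1.0 / (config.adult_age + 1.0))
    return RunReport(
        config=config,
        feature_results=feature_results,
        confidences=confidences,
        weights=weights,
        lambdas=lambdas,
        lambda_line=line,
        fit_groups=fit_groups,
        eval_groups=eval_groups,
        models=models,
        predictions=predictions,
        predicted_ages=horvath_inverse(np.clip(predictions, lo, None), config.adult_age),
        mae_per_group=mae_per_group,
        mae_eval=mae_eval,
        mae_overall=mae_overall,
        transcript=transcript,
        audit=audit,
        timings=timings,
    )


def run_centralized_wenda(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: RunConfig | None = None,
    similarity: Mapping[str, float] | None = None,
    ground_truth: Mapping | None = None,
) -> RunReport:
    """Non-federated reference path: pooled data, direct closed forms, the
    same gradient trainer.  With a single source client the federated
    pipeline reproduces this path to numerical precision."""
    config = config or RunConfig()
    config.validate()
    _check_inputs(sources, target)
    timings: dict[str, float] = {}
    if similarity is None and ground_truth is not None:
        similarity = ground_truth.get("similarity")

    X_pool = np.vstack([s.X for s in sources])
    y_pool = np.concatenate([s.y for s in sources])
    pooled = DomainDataset(X_pool, y_pool, None, domain_id="pooled-source",
                           feature_names=sources[0].feature_names)

    t0 = time.perf_counter()
    feature_results = _phase1_centralized(pooled, target, config)
    timings["phase1_feature_models"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    confidences, weights = _phase2_weights(feature_results, target, config)
    timings["phase2_weights"] = time.perf_counter() - t0

    clients = {"s00": (pooled.X, pooled.y)}

    def train_fn(weight_values: np.ndarray, lam: float) -> WENModel:
        return train_federated_wen(clients, weight_values, lam, config.alpha, config.schedule)

    def cv_fn(weight_values: np.ndarray) -> float:
        return cv_select_lambda(
            clients,
            weight_values,
            config.lambda_grid,
            folds=config.cv_folds,
            alpha=config.alpha,
            schedule=config.schedule,
            adult_age=config.adult_age,
            seed=config.seed,
        )

    groups = sorted(str(g) for g in np.unique(target.groups))
    fit_groups_cfg = tuple(
        str(g) for g in (config.fit_groups or ((groups[0], groups[-1]) if config.lambda_mode == "prior-knowledge" else ()))
    )
    fit_labels = _fit_labels_from_ground_truth(ground_truth, target, fit_groups_cfg)

    t0 = time.perf_counter()
    lambdas, line, fit_groups, eval_groups, models, predictions = _phase34(
        train_fn, weights, target, config, similarity, fit_labels, cv_fn=cv_fn
    )
    timings["phase3_phase4_training"] = time.perf_counter() - t0

    y_true = None if ground_truth is None else ground_truth.get("y_target")
    mae_per_group, mae_eval, mae_overall = _evaluate(
        predictions, target, y_true, fit_groups, config
    )
    lo = np.log(1.0 / (config.adult_age + 1.0))
    return RunReport(
        config=config,
        feature_results=feature_results,
        confidences=confidences,
        weights=weights,
        lambdas=lambdas,
        lambda_line=line,
        fit_groups=fit_groups,
        eval_groups=eval_groups,
        models=models,
        predictions=predictions,
        predicted_ages=horvath_inverse(np.clip(predictions, lo, None), config.adult_age),
        mae_per_group=mae_per_group,
        mae_eval=mae_eval,
        mae_overall=mae_overall,
        transcript=None,
        audit=None,
        timings=timings,
    )
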