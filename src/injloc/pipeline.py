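"""End-to-end orchestration: simulate → featurize → train → evaluate →
diagnose → impute → estimate → report.

Each stage is an ordinary function over the library's containers, so
stages can be rerun individually; :func:`run_pipeline` chains them,
persists every stage's CSV artifacts, and writes a machine-readable run
manifest (config hash, derived stage seeds, artifact checksums).  All
stage seeds derive deterministically from the single global seed, so a
rerun with the same config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation as est
from . import harness, text
from .records import (LOCATION_CLASSES, MISSING, RecordSet, apply_exclusions,
                      partition_by_missingness, recode_records, write_records)
from .diagnostics import diagnostics_summary, influential_words, rank_word_frequencies
from .synthetic import (GeneratorConfig, MissingnessModel, TruthTable,
                        default_missingness_model, generate_world,
                        nonignorable_missingness_model)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "train", "evaluate", "diagnose", "impute",
          "estimate", "report")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31: crc32 of the stage name folded
    into the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class FeatureSettings:
    min_count: int = 10
    min_doc_fraction: float = 0.0
    ngram_range: tuple[int, int] = (1, 2)
    embedding_dim: int = 50
    embedding_epochs: int = 15
    scopes: tuple[str, ...] = ("shared", "all")
    constructions: tuple[str, ...] = ("tfidf", "ngram", "embedding")


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    split: harness.SplitSpec = field(default_factory=harness.SplitSpec)
    families: tuple[str, ...] = harness.FAMILIES
    estimation: EstimationConfig = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if self.estimation is None:
            self.estimation = est.EstimationConfig(years=self.generator.years)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        seed = int(d.get("seed", 0))
        gen_kwargs = dict(d.get("generator", {}))
        miss = gen_kwargs.pop("missingness", None)
        if "years" in gen_kwargs:
            gen_kwargs["years"] = tuple(gen_kwargs["years"])
        if "location_shares" in gen_kwargs:
            gen_kwargs["location_shares"] = tuple(gen_kwargs["location_shares"])
        if "replacement_events" in gen_kwargs:
            gen_kwargs["replacement_events"] = [
                tuple(e) for e in gen_kwargs["replacement_events"]]
        gen = GeneratorConfig(seed=derive_seed(seed, "simulate"), **gen_kwargs)
        if miss == "nonignorable":
            gen.missingness_model = nonignorable_missingness_model()
        elif isinstance(miss, dict):
            gen.missingness_model = MissingnessModel(**miss)
        feat_kwargs = dict(d.get("features", {}))
        for k in ("ngram_range", "scopes", "constructions"):
            if k in feat_kwargs:
                feat_kwargs[k] = tuple(feat_kwargs[k])
        features = FeatureSettings(**feat_kwargs)
        split = harness.SplitSpec(seed=derive_seed(seed, "train"),
                                  **d.get("split", {}))
        est_kwargs = dict(d.get("estimation", {}))
        if "years" in est_kwargs:
            est_kwargs["years"] = tuple(est_kwargs["years"])
        else:
            est_kwargs["years"] = gen.years
        est_cfg = est.EstimationConfig(seed=derive_seed(seed, "estimate"),
                                       **est_kwargs)
        families = tuple(d.get("families", harness.FAMILIES))
        return cls(generator=gen, features=features, split=split,
                   families=families, estimation=est_cfg, seed=seed)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# Stage functions
# --------------------------------------------------------------------------

def prepare_world(gen_config: GeneratorConfig) -> tuple[RecordSet, TruthTable]:
    """Simulate, apply the BB/non-GSW exclusion, and recode locations."""
    rs, truth = generate_world(gen_config)
    rs = apply_exclusions(rs)
    rs = recode_records(rs)
    return rs, truth


def tokenize_records(rs: RecordSet) -> list[list[str]]:
    return [text.tokenize(t) for t in rs.records["narrative"]]


@dataclass
class FeatureBundle:
    label: str
    vocab: text.Vocabulary
    train: text.FeatureMatrix
    test: text.FeatureMatrix
    missing: text.FeatureMatrix


def build_feature_bundles(tok_missing, tok_train, tok_test,
                          missing_ids, train_ids, test_ids,
                          settings: FeatureSettings,
                          seed: int) -> dict[str, FeatureBundle]:
    """Construct every (scope × construction) predictor set.

    Vocabularies are filtered on the missing vs nonmissing corpora; TF-IDF
    document frequencies are frozen on the training corpus; GloVe vectors
    are trained on the pooled corpus (unsupervised, so no label leakage).
    """
    tok_nonmissing = tok_train + tok_test
    bundles: dict[str, FeatureBundle] = {}
    for scope in settings.scopes:
        vocab_uni = text.build_vocabulary(tok_missing, tok_nonmissing, scope,
                                          settings.min_count,
                                          settings.min_doc_fraction)
        for construction in settings.constructions:
            label = f"{scope}:{construction}"
            if construction == "tfidf":
                w = text.TfidfWeighter(vocab_uni).fit(tok_train)
                fm_tr = w.transform(tok_train, train_ids)
                fm_te = w.transform(tok_test, test_ids)
                fm_mi = w.transform(tok_missing, missing_ids)
                vocab = vocab_uni
            elif construction == "ngram":
                ng = settings.ngram_range
                exp_m = [text.add_ngrams(d, ng) for d in tok_missing]
                exp_nm = [text.add_ngrams(d, ng) for d in tok_nonmissing]
                vocab = text.build_vocabulary(exp_m, exp_nm, scope,
                                              settings.min_count,
                                              settings.min_doc_fraction)
                exp_tr = [text.add_ngrams(d, ng) for d in tok_train]
                w = text.TfidfWeighter(vocab).fit(exp_tr)
                fm_tr = w.transform(exp_tr, train_ids)
                fm_te = w.transform([text.add_ngrams(d, ng) for d in tok_test],
                                    test_ids)
                fm_mi = w.transform([text.add_ngrams(d, ng) for d in tok_missing],
                                    missing_ids)
                fm_tr = text.FeatureMatrix(fm_tr.values, fm_tr.feature_names,
                                           fm_tr.record_ids, "ngram")
                fm_te = text.FeatureMatrix(fm_te.values, fm_te.feature_names,
                                           fm_te.record_ids, "ngram")
                fm_mi = text.FeatureMatrix(fm_mi.values, fm_mi.feature_names,
                                           fm_mi.record_ids, "ngram")
            else:  # embedding
                glove = text.GloveModel(vocab_uni, dim=settings.embedding_dim,
                                        epochs=settings.embedding_epochs,
                                        seed=derive_seed(seed, f"glove:{scope}"))
                glove.fit(tok_nonmissing + tok_missing)
                fm_tr = glove.transform(tok_train, train_ids)
                fm_te = glove.transform(tok_test, test_ids)
                fm_mi = glove.transform(tok_missing, missing_ids)
                vocab = vocab_uni
            bundles[label] = FeatureBundle(label, vocab, fm_tr, fm_te, fm_mi)
    return bundles


def quick_fit_predict(X_train, y_labels, X_target, family: str, params: dict,
                      seed: int) -> np.ndarray:
    """Fit one estimator at fixed hyperparameters and return (n, 4)
    probabilities on the target matrix, tolerating absent classes (their
    probability columns are zero) — used inside bootstrap replications
    where a small resample may lose a rare class."""
    codes = np.asarray([harness.CLASS_INDEX[c] for c in y_labels])
    estimator = harness._make_estimator(family, params, seed)
    estimator.fit(X_train, codes)
    proba_present = estimator.predict_proba(X_target)
    present = list(estimator.classes_)
    proba = np.zeros((X_target.shape[0], 4))
    for j, cls in enumerate(present):
        proba[:, int(cls)] = proba_present[:, j]
    return proba


def make_adjusted_closure(family: str, params: dict, scope: str,
                          settings: FeatureSettings,
                          token_lookup: dict[str, list[str]],
                          config: est.EstimationConfig,
                          replacement_log: list | None = None,
                          refit_vocabulary: bool = False,
                          base_records: RecordSet | None = None):
    """Build the train→predict→estimate closure the bootstrap reruns.

    Each call refits the preferred model at its selected hyperparameters
    on the resampled labeled records, re-predicts the resampled missing
    records, and recomputes the adjusted estimates.  By default the
    featurization (vocabulary and document frequencies) is frozen from the
    full data and only the classifier is refit per replication;
    ``refit_vocabulary=True`` rebuilds both inside every replication.
    ``token_lookup`` maps base record ids to pre-tokenized narratives;
    resampled ids carry a ``#b`` suffix.
    """

    def tokens_for(ids) -> list[list[str]]:
        return [token_lookup[i.split("#")[0]] for i in ids]

    frozen: dict = {}
    if not refit_vocabulary:
        # featurize every base record once; replications slice rows
        base_ids = list(token_lookup)
        frozen["row_of"] = {rid: i for i, rid in enumerate(base_ids)}
        frozen["tokens"] = [token_lookup[rid] for rid in base_ids]
        if base_records is not None:
            missing0, nonmissing0 = partition_by_missingness(base_records)
            tok_m0 = tokens_for(missing0.records["record_id"])
            tok_nm0 = tokens_for(nonmissing0.records["record_id"])
            vocab0 = text.build_vocabulary(tok_m0, tok_nm0, scope,
                                           settings.min_count,
                                           settings.min_doc_fraction)
            w0 = text.TfidfWeighter(vocab0).fit(tok_nm0)
            frozen["X"] = w0.transform(frozen["tokens"]).values

    def closure(rs_b: RecordSet, seed: int) -> pd.DataFrame:
        missing, nonmissing = partition_by_missingness(rs_b)
        if refit_vocabulary:
            tok_m = tokens_for(missing.records["record_id"])
            tok_nm = tokens_for(nonmissing.records["record_id"])
            vocab = text.build_vocabulary(tok_m, tok_nm, scope,
                                          settings.min_count,
                                          settings.min_doc_fraction)
            w = text.TfidfWeighter(vocab).fit(tok_nm)
            X_nm = w.transform(tok_nm).values
            X_m = w.transform(tok_m).values
        else:
            if "X" not in frozen:
                tok_m0 = tokens_for(missing.records["record_id"])
                tok_nm0 = tokens_for(nonmissing.records["record_id"])
                vocab = text.build_vocabulary(tok_m0, tok_nm0, scope,
                                              settings.min_count,
                                              settings.min_doc_fraction)
                w = text.TfidfWeighter(vocab).fit(tok_nm0)
                frozen["X"] = w.transform(frozen["tokens"]).values
            row_of = frozen["row_of"]
            rows_nm = [row_of[i.split("#")[0]]
                       for i in nonmissing.records["record_id"]]
            rows_m = [row_of[i.split("#")[0]]
                      for i in missing.records["record_id"]]
            X_nm = frozen["X"][rows_nm]
            X_m = frozen["X"][rows_m]
        proba = quick_fit_predict(X_nm, nonmissing.records["location4"],
                                  X_m, family, params, seed)
        pred = np.asarray(LOCATION_CLASSES, dtype=object)[np.argmax(proba, axis=1)]
        predictions = pd.DataFrame({"record_id": missing.records["record_id"],
                                    "predicted": pred})
        assigned = est.combine_locations(rs_b, predictions)
        if config.replacement_correction and replacement_log:
            assigned, _ = est.impute_replacement_hospitals(assigned,
                                                           replacement_log)
        return est.weighted_annual_estimates(assigned, config, adjusted=True)

    return closure


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage, writing artifacts and a manifest under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "global_seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "stages_complete": [],
        "artifacts": {},
    }

    def record_stage(stage: str, *paths: Path) -> None:
        manifest["stages_complete"].append(stage)
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # -- simulate
        rs, truth = prepare_world(config.generator)
        rec_path = out / "records.csv"
        write_records(rs, rec_path)
        truth_path = out / "truth.csv"
        truth.true_locations.rename_axis("record_id").to_frame().assign(
            masked=lambda d: d.index.isin(truth.masked_ids)
        ).to_csv(truth_path)
        record_stage("simulate", rec_path, truth_path)

        # -- featurize
        missing, nonmissing = partition_by_missingness(rs)
        train, test = harness.split_train_test(nonmissing, config.split)
        tok_missing = tokenize_records(missing)
        tok_train = tokenize_records(train)
        tok_test = tokenize_records(test)
        bundles = build_feature_bundles(
            tok_missing, tok_train, tok_test,
            list(missing.records["record_id"]),
            list(train.records["record_id"]),
            list(test.records["record_id"]),
            config.features, derive_seed(config.seed, "featurize"))
        vocab_path = out / "vocabularies.csv"
        pd.DataFrame([{"feature_set": b.label, "scope": b.vocab.scope,
                       "n_terms": len(b.vocab),
                       "n_missing_corpus_terms": b.vocab.source_sizes[0],
                       "n_nonmissing_corpus_terms": b.vocab.source_sizes[1]}
                      for b in bundles.values()]).to_csv(vocab_path, index=False)
        record_stage("featurize", vocab_path)

        # -- train + evaluate
        specs = [harness.ModelSpec(f, seed=derive_seed(config.seed, "train"))
                 for f in config.families]
        grid = harness.run_model_grid(
            {lbl: (b.train, b.test) for lbl, b in bundles.items()},
            list(train.records["location4"]), list(test.records["location4"]),
            specs)
        grid_path = out / "model_grid.csv"
        grid.table().to_csv(grid_path, index=False)
        record_stage("train", grid_path)
        record_stage("evaluate")

        # -- diagnose
        best_family, best_fs = grid.best_key
        any_vocab = bundles[best_fs].vocab
        rfl_m = rank_word_frequencies(tok_missing, any_vocab, "missing")
        rfl_nm = rank_word_frequencies(tok_train + tok_test, any_vocab,
                                       "nonmissing")
        diag = diagnostics_summary(rfl_m, rfl_nm, top_k=200)
        diag_path = out / "diagnostics.csv"
        pd.DataFrame([diag]).to_csv(diag_path, index=False)
        infl_path = out / "influential_words.csv"
        lasso_key = next((k for k in grid.models
                          if k[0] == "lasso_multinomial"
                          and k[1].endswith("tfidf")), None)
        if lasso_key:
            frames = []
            for c in LOCATION_CLASSES:
                f = influential_words(grid.models[lasso_key], c, top_n=10)
                f.insert(0, "location", c)
                frames.append(f)
            pd.concat(frames, ignore_index=True).to_csv(infl_path, index=False)
            record_stage("diagnose", diag_path, infl_path)
        else:
            record_stage("diagnose", diag_path)

        # -- impute
        best_model = grid.models[grid.best_key]
        predictions = harness.predict_missing(best_model,
                                              bundles[best_fs].missing)
        pred_path = out / "predictions.csv"
        predictions.to_csv(pred_path, index=False)
        record_stage("impute", pred_path)

        # -- estimate
        assigned = est.combine_locations(rs, predictions)
        if config.estimation.replacement_correction and truth.replacement_log:
            assigned, factors = est.impute_replacement_hospitals(
                assigned, truth.replacement_log)
        unadjusted = est.weighted_annual_estimates(rs.records, config.estimation,
                                                   adjusted=False)
        adjusted = est.weighted_annual_estimates(assigned, config.estimation,
                                                 adjusted=True)
        token_lookup = {rid: tok for rid, tok in zip(
            list(missing.records["record_id"]) + list(train.records["record_id"])
            + list(test.records["record_id"]),
            tok_missing + tok_train + tok_test)}
        scope = best_fs.split(":")[0]
        closure = make_adjusted_closure(
            best_family, best_model.best_params, scope, config.features,
            token_lookup, config.estimation,
            replacement_log=truth.replacement_log, base_records=rs)
        cis = est.bootstrap_ci(rs, closure, config.estimation)
        adjusted = adjusted.drop(columns=["ci_low", "ci_high"]).merge(
            cis[["location", "ci_low", "ci_high"]], on="location", how="left")
        est_path = out / "estimates.csv"
        pd.concat([adjusted, unadjusted], ignore_index=True).to_csv(
            est_path, index=False)
        record_stage("estimate", est_path)

        # -- report
        strat_frames = []
        for by in ("intent", "race", "sex"):
            strat_frames.append(est.stratified_estimates(
                assigned, by, config.estimation, adjusted=True))
            strat_frames.append(est.stratified_estimates(
                rs.records[rs.records["location4"] != MISSING], by,
                config.estimation, adjusted=False))
        strat_path = out / "stratified_estimates.csv"
        pd.concat(strat_frames, ignore_index=True).to_csv(strat_path, index=False)
        adj_shares = dict(zip(adjusted["location"], adjusted["share"]))
        unadj_shares = dict(zip(unadjusted["location"], unadjusted["share"]))
        statistic, p = est.compare_distributions_chi2(
            adj_shares, unadj_shares, n_effective=len(rs))
        cmp_path = out / "comparison.csv"
        pd.DataFrame([{"chi2": statistic, "p": p,
                       "significant": p < config.estimation.alpha}]).to_csv(
            cmp_path, index=False)
        record_stage("report", strat_path, cmp_path)
    except Exception as exc:
        failed = STAGES[len(manifest["stages_complete"])]
        manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = {"seed": config.seed, "families": list(config.families)}
    for name, sub in (("generator", config.generator),
                      ("features", config.features),
                      ("split", config.split),
                      ("estimation", config.estimation)):
        try:
            d[name] = json.loads(json.dumps(asdict(sub), default=str))
        except TypeError:
            d[name] = str(sub)
    return d
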