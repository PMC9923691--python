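"""File formats, run configuration, and the end-to-end pipeline.

Formats are deliberately plain: embeddings in word2vec text, taxonomies in
Newick, ERP arrays as raw float64 with a JSON sidecar, everything else TSV
or JSON.  Item order is the single source of alignment across files — no
per-file reordering happens anywhere.  ``run_pipeline`` chains the whole
analysis (simulate -> encode x3 -> compare -> kernel PCA -> decode ->
patterns) and writes a report tree that is bit-identical across reruns of
the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding as _dec
from . import encoding as _enc
from . import simulate as _sim
from . import spaces as _sp

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_embeddings",
    "write_embeddings",
    "read_taxonomy",
    "write_taxonomy",
    "read_erp",
    "write_erp",
    "read_covariates",
    "write_covariates",
    "write_similarity",
    "read_similarity",
    "run_pipeline",
]

logger = logging.getLogger("erpsem")

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Embeddings: word2vec text format
# ---------------------------------------------------------------------------

def write_embeddings(space: _sp.EmbeddingSpace, path) -> None:
    """Write word2vec text: header ``n_words dims``, then one word per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{space.n_words} {space.dims}\n")
        for word, row in zip(space.words, space.matrix):
            fh.write(word + " " + " ".join(FLOAT_FMT % v for v in row) + "\n")


def read_embeddings(path) -> _sp.EmbeddingSpace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header 'n_words dims'")
        try:
            n_words, dims = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ValueError(f"{path}:1: non-integer header") from exc
        words: list[str] = []
        rows = np.empty((n_words, dims))
        seen: set[str] = set()
        lineno = 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if lineno - 2 >= n_words:
                raise ValueError(f"{path}:{lineno}: more rows than header declares")
            parts = line.split()
            word, vals = parts[0], parts[1:]
            if len(vals) != dims:
                raise ValueError(
                    f"{path}:{lineno}: expected {dims} values, got {len(vals)}"
                )
            if word in seen:
                raise ValueError(f"{path}:{lineno}: duplicate word {word!r}")
            seen.add(word)
            try:
                rows[len(words)] = [float(v) for v in vals]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token") from exc
            words.append(word)
        if len(words) != n_words:
            raise ValueError(
                f"{path}:{lineno + 1}: header declares {n_words} words, "
                f"file has {len(words)}"
            )
    return _sp.EmbeddingSpace(words, rows)


# ---------------------------------------------------------------------------
# Taxonomy: Newick
# ---------------------------------------------------------------------------

def write_taxonomy(tree: _sp.TaxonomyTree, path) -> None:
    Path(path).write_text(tree.to_newick())


def read_taxonomy(path) -> _sp.TaxonomyTree:
    return _sp.TaxonomyTree.from_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# ERP arrays: raw float64 + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_erp(erp: _enc.ERPDataset, path) -> None:
    path = Path(path)
    np.ascontiguousarray(erp.data, dtype="<f8").tofile(path)
    meta = {
        "n_items": erp.n_items,
        "n_sensors": erp.n_sensors,
        "n_times": erp.n_times,
        "rate_hz": erp.rate_hz,
        "t_start_ms": erp.t_start_ms,
        "sensor_labels": erp.sensor_labels,
        "words": erp.words,
        "dtype": "<f8",
        "order": "items,sensors,times (C)",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def read_erp(path) -> _enc.ERPDataset:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing ERP sidecar: expected {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = (meta["n_items"], meta["n_sensors"], meta["n_times"])
    data = np.fromfile(path, dtype=meta.get("dtype", "<f8"))
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"{path}: sidecar declares {shape} = {int(np.prod(shape))} values, "
            f"file has {data.size}"
        )
    return _enc.ERPDataset(
        words=meta["words"],
        data=data.reshape(shape),
        rate_hz=meta["rate_hz"],
        t_start_ms=meta["t_start_ms"],
        sensor_labels=meta["sensor_labels"],
    )


# ---------------------------------------------------------------------------
# Covariates and similarity matrices: TSV
# ---------------------------------------------------------------------------

def write_covariates(cov: _sim.Covariates, path) -> None:
    df = pd.DataFrame(
        {
            "word": cov.words,
            "log_frequency": cov.log_frequency,
            "concreteness": cov.concreteness,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path) -> _sim.Covariates:
    df = pd.read_csv(path, sep="\t")
    return _sim.Covariates(
        list(df["word"].astype(str)),
        df["log_frequency"].to_numpy(float),
        df["concreteness"].to_numpy(float),
    )


def write_similarity(sim: _sp.SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.words, columns=sim.words)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=f"#{sim.kind}")


def read_similarity(path) -> _sp.SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = str(df.index.name or "").lstrip("#") or "cosine"
    values = df.to_numpy(float)
    values = (values + values.T) / 2.0  # text roundtrip can break symmetry
    if kind in ("cosine", "path"):
        np.fill_diagonal(values, 1.0)
    return _sp.SimilarityMatrix(list(df.columns.astype(str)), values, kind=kind)


def _write_matrix_tsv(matrix: np.ndarray, path, columns, index=None) -> None:
    df = pd.DataFrame(np.asarray(matrix), columns=list(columns))
    if index is not None:
        df.insert(0, "id", list(index))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A fully serializable description of one pipeline run.

    A saved config re-runs the identical analysis: all randomness flows
    from ``seed``, and the synthetic preset/overrides pin the inputs.  If
    ``embeddings_path``/``erp_path``/... are given, those files are used
    instead of simulating.
    """

    seed: int = 0
    preset: str | None = "german"
    n_words: int | None = None
    n_sensors: int | None = None
    folds: int = 10
    penalty: float = _enc.DEFAULT_PENALTY
    window_ms: tuple[float, float] = _enc.DEFAULT_WINDOW_MS
    k_components: int = 8
    feature_kind: str = "vectors"  # vectors | dual
    noise_sd: float = _sim.DEFAULT_NOISE_SD
    factor_snr: float = _sim.DEFAULT_FACTOR_SNR
    taxonomy_fidelity: float = _sim.DEFAULT_TAXONOMY_FIDELITY
    embeddings_path: str | None = None
    taxonomy_path: str | None = None
    erp_path: str | None = None
    covariates_path: str | None = None
    out_dir: str = "erpsem_out"
    n_boot: int = 10_000
    top_words: int = 7

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["window_ms"] = list(self.window_ms)
        return json.dumps(d, indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "window_ms" in d:
            d["window_ms"] = tuple(d["window_ms"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Stages: obtain inputs (simulate unless files are given) -> encode the
    ERP from vector, taxonomy and covariate-augmented features -> compare
    vector vs. taxonomy models -> kernel PCA of the cosine kernel ->
    window + time-resolved decoding -> decoder patterns.  All outputs land
    under ``config.out_dir``; the returned dict is also written as
    ``report.json``.  Reruns of the same config are bit-identical.
    """
    out = Path(config.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "encoding").mkdir(exist_ok=True)
    (out / "decoding").mkdir(exist_ok=True)
    config.save(out / "config.json")
    logger.info("run_pipeline: seed=%d preset=%s out=%s",
                config.seed, config.preset, out)

    with _stage("inputs"):
        if config.embeddings_path:
            space = read_embeddings(config.embeddings_path)
            taxonomy = read_taxonomy(config.taxonomy_path)
            erp = read_erp(config.erp_path)
            covariates = read_covariates(config.covariates_path)
            truth = None
        else:
            bundle = _sim.simulate_bundle(
                preset=config.preset,
                seed=config.seed,
                n_words=config.n_words,
                n_sensors=config.n_sensors,
                factor_snr=config.factor_snr,
                noise_sd=config.noise_sd,
                taxonomy_fidelity=config.taxonomy_fidelity,
            )
            space, taxonomy, erp, covariates, truth = (
                bundle.space, bundle.taxonomy, bundle.erp,
                bundle.covariates, bundle.truth,
            )
            write_embeddings(space, out / "inputs" / "embeddings.txt")
            write_taxonomy(taxonomy, out / "inputs" / "taxonomy.nwk")
            write_erp(erp, out / "inputs" / "erp.dat")
            write_covariates(covariates, out / "inputs" / "covariates.tsv")
            np.savetxt(out / "inputs" / "factor_loadings.tsv",
                       truth.factor_loadings, fmt=FLOAT_FMT, delimiter="\t")
        if list(space.words) != list(erp.words):
            raise ValueError("embedding and ERP word lists are not aligned")

    folds = _enc.make_folds(space.words, config.folds, config.seed)

    with _stage("encode"):
        if config.feature_kind == "vectors":
            vec_features = space.matrix
        elif config.feature_kind == "dual":
            vec_features = _sp.dual_transform(space).values
        else:
            raise ValueError(f"unknown feature_kind {config.feature_kind!r}")
        tax_features = _sp.path_similarity_matrix(taxonomy, space.words).values
        aug_features = _enc.augment_features(vec_features, space.words, covariates)
        kw = dict(penalty=config.penalty, window_ms=config.window_ms,
                  n_boot=config.n_boot)
        enc_vec = _enc.encode_cv(erp, vec_features, folds, **kw)
        enc_tax = _enc.encode_cv(erp, tax_features, folds, **kw)
        enc_aug = _enc.encode_cv(erp, aug_features, folds, **kw)
        for name, res in [("vector", enc_vec), ("taxonomy", enc_tax),
                          ("augmented", enc_aug)]:
            _write_matrix_tsv(res.scores, out / "encoding" / f"{name}_scores.tsv",
                              columns=[FLOAT_FMT % t for t in res.time_ms])
            _write_matrix_tsv(res.ci, out / "encoding" / f"{name}_ci.tsv",
                              columns=["lo", "hi"])
        _write_matrix_tsv(
            enc_vec.electrode_window_scores()[:, None],
            out / "encoding" / "electrode_window_scores.tsv",
            columns=["window_signed_r2"], index=erp.sensor_labels,
        )

    with _stage("compare"):
        comparison = _enc.compare_models(enc_vec, enc_tax)

    with _stage("kernel_pca"):
        kernel = _sp.cosine_kernel(space)
        components = _sp.kernel_pca(kernel, config.k_components)
        _write_matrix_tsv(
            components.scores, out / "decoding" / "component_scores.tsv",
            columns=[f"c{j+1}" for j in range(components.k)], index=space.words,
        )
        top = {}
        for j in range(components.k):
            pos, neg = _sp.top_scoring_words(components, j, m=config.top_words)
            top[f"c{j+1}"] = {"positive": pos, "negative": neg}

    with _stage("decode"):
        window_feats = _dec.extract_window_features(erp, *config.window_ms)
        dec_win = _dec.decode_components_cv(
            window_feats.matrix, components, folds,
            penalty=config.penalty, n_boot=config.n_boot,
        )
        dec_time = _dec.decode_timecourse(erp, components, folds,
                                          penalty=config.penalty)
        _write_matrix_tsv(dec_win.window_scores,
                          out / "decoding" / "window_scores.tsv",
                          columns=[f"c{j+1}" for j in range(components.k)])
        _write_matrix_tsv(dec_win.component_ci,
                          out / "decoding" / "component_ci.tsv",
                          columns=["lo", "hi"])
        np.ascontiguousarray(dec_time.time_scores, dtype="<f8").tofile(
            out / "decoding" / "time_scores.dat")
        (out / "decoding" / "time_scores.dat.json").write_text(json.dumps({
            "shape": list(dec_time.time_scores.shape),
            "axes": ["fold", "component", "timepoint"],
            "dtype": "<f8",
            "time_ms": [float(t) for t in dec_time.time_ms],
        }, indent=1) + "\n")

    with _stage("patterns"):
        W, Xs = _dec.fit_window_decoder(erp, components, *config.window_ms,
                                        penalty=config.penalty)
        for mode in ("zscore", "haufe"):
            pat = _dec.decoder_patterns(W, Xs, mode=mode,
                                        sensor_labels=erp.sensor_labels)
            _write_matrix_tsv(pat.values,
                              out / "decoding" / f"patterns_{mode}.tsv",
                              columns=[f"c{j+1}" for j in range(components.k)],
                              index=erp.sensor_labels)

    prestim = _enc.window_average(enc_vec, erp.t_start_ms, 0.0)
    mean_time = dec_time.mean_time_scores  # k x T
    peaks_ms = [float(dec_time.time_ms[int(np.argmax(mean_time[c]))])
                for c in range(components.k)]
    report = {
        "config": json.loads(config.to_json()),
        "encoding": {
            "vector_window_mean": enc_vec.mean_window_score,
            "taxonomy_window_mean": enc_tax.mean_window_score,
            "augmented_window_mean": enc_aug.mean_window_score,
            "vector_prestimulus_mean": float(prestim.mean()),
            "vector_window_p": enc_vec.test.p_value,
            "taxonomy_window_p": enc_tax.test.p_value,
            "window_means_per_fold": [float(v) for v in enc_vec.window_means],
        },
        "comparison": {
            "mean_difference": comparison.mean_difference,
            "folds_vector_better": comparison.folds_a_better,
            "n_folds": config.folds,
            "p_value": comparison.test.p_value,
        },
        "kernel_pca": {
            "eigenvalues": [float(v) for v in components.eigenvalues],
            "top_words": top,
        },
        "decoding": {
            "ci_level": dec_win.ci_level,
            "mean_window_scores": [float(v) for v in dec_win.mean_window_scores],
            "component_ci": [[float(a), float(b)] for a, b in dec_win.component_ci],
            "significant": [bool(b) for b in dec_win.significant],
            "time_peak_ms": peaks_ms,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
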