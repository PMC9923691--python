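"""Synthetic word-semantics + ERP fixtures with a planted forward model.

The real item-level ERP datasets this pipeline targets (hundreds of nouns,
tens of sensors, subject-averaged epochs) are not redistributable, so this
module builds structurally faithful stand-ins end to end:

* an embedding space whose rows are a small number of latent semantic
  factors mixed into ``dims`` axes plus isotropic noise,
* a taxonomy whose path distances agree with embedding distances only to a
  tunable degree (``fidelity``), mimicking how a hand-built hyponymy tree
  tracks distributional similarity imperfectly,
* lexical covariates (log frequency, concreteness), optionally correlated
  with a planted factor,
* item-level ERPs in which a chosen subset of the factors drives sensor
  amplitudes through a linear spatial mixing and an N400-like temporal
  bump, plus Gaussian sensor noise.

Because the forward model is planted, every downstream claim (encoding
recovers the window, decoding recovers exactly the planted components,
nulls calibrate to zero) can be tested as parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .spaces import EmbeddingSpace, TaxonomyTree, cosine_kernel

__all__ = [
    "GroundTruth",
    "Covariates",
    "SyntheticBundle",
    "PRESETS",
    "generate_embeddings",
    "plant_forward_model",
    "generate_taxonomy",
    "generate_erp",
    "generate_covariates",
    "simulate_bundle",
]

# --- study-condition defaults -------------------------------------------------
DEFAULT_DIMS = 50           # embedding axes (scaled down from typical 300)
DEFAULT_K_TRUE = 8          # planted latent factors; 8 factors are analyzed
DEFAULT_FACTOR_SNR = 4.0    # factor-explained variance / embedding noise variance
FACTOR_VAR_DECAY = 0.8      # geometric decay of factor variances (see methods)
DEFAULT_PLANTED = (0, 1, 2)  # factors wired into the ERP forward model
DEFAULT_EFFECT_WINDOW_MS = (300.0, 500.0)  # N400 window
DEFAULT_NOISE_SD = 2.0      # post-averaging residual sensor noise, microvolts;
                            # calibrated so scaled-down window encoding scores
                            # land near 0.05-0.1 (see docs/methods.md)
DEFAULT_EPOCH_MS = (-100.0, 920.0)
DEFAULT_RATE_HZ = 200.0
DEFAULT_TAXONOMY_FIDELITY = 0.5
CONCRETENESS_FACTOR_CORR = (0, 0.5)  # concreteness tracks the leading factor

#: Shapes of the two experiments the generator emulates:
#: a large sparse-montage study and a smaller high-density one.
PRESETS: dict[str, dict] = {
    "english": {"n_words": 960, "n_sensors": 28},
    "german": {"n_words": 150, "n_sensors": 64},
}


@dataclass
class GroundTruth:
    """Everything planted into a synthetic fixture, for recovery checks."""

    factor_loadings: np.ndarray | None = None  # items x k_true latent factors
    loading_directions: np.ndarray | None = None  # k_true x dims, orthonormal rows
    mixing: np.ndarray | None = None  # dims x sensors spatial pattern
    planted_factors: tuple[int, ...] = ()
    temporal_profile: np.ndarray | None = None  # per timepoint, in [0, 1]
    effect_window_ms: tuple[float, float] = DEFAULT_EFFECT_WINDOW_MS
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0


@dataclass
class Covariates:
    """Per-word lexical covariates used to augment encoding features."""

    words: list[str]
    log_frequency: np.ndarray
    concreteness: np.ndarray

    def __post_init__(self) -> None:
        self.words = list(self.words)
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words in covariates")
        self.log_frequency = np.asarray(self.log_frequency, dtype=float)
        self.concreteness = np.asarray(self.concreteness, dtype=float)
        n = len(self.words)
        if self.log_frequency.shape != (n,) or self.concreteness.shape != (n,):
            raise ValueError("one covariate value required per word")


def _child_seeds(seed: int, n: int) -> list[int]:
    # deterministic per-component child seeds below 2**31
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def factor_variances(k_true: int, decay: float = FACTOR_VAR_DECAY) -> np.ndarray:
    """Planted factor variances: geometric decay, normalized to sum to k.

    A strictly ordered spectrum keeps the kernel eigenvalues non-degenerate
    so the factors are identifiable as individual components; equal
    variances would leave the factor subspace rotationally ambiguous.
    """
    v = decay ** np.arange(k_true, dtype=float)
    return k_true * v / v.sum()


#: Shared mean offset, in multiples of the per-row signal+noise sd.  Real
#: distributional embeddings have a large common mean component and row
#: norms concentrated around it; without it, norm variation across words
#: would make the cosine kernel a distorted image of the factor structure.
EMBEDDING_MEAN_SCALE = 2.0


def generate_embeddings(
    n_words: int,
    dims: int = DEFAULT_DIMS,
    k_true: int = DEFAULT_K_TRUE,
    factor_snr: float = DEFAULT_FACTOR_SNR,
    seed: int = 0,
) -> tuple[EmbeddingSpace, GroundTruth]:
    """Embeddings = latent factor loadings x orthonormal directions + noise.

    The factor-loading columns are constructed exactly orthogonal in-sample
    (latent factors are uncorrelated by design) with sample variances
    ``factor_variances(k_true)``; isotropic Gaussian noise is scaled so
    total factor-explained variance over total noise variance equals
    ``factor_snr``, and a shared mean offset along a direction orthogonal
    to all factors emulates the common component of real embeddings.
    ``factor_snr=0`` yields pure noise (factors still returned, but
    carrying no signal).
    """
    if n_words < 1 or dims < 1 or k_true < 1:
        raise ValueError("n_words, dims and k_true must be positive")
    if not (k_true <= n_words and k_true < dims):
        raise ValueError("need n_words >= k_true and dims > k_true")
    if factor_snr < 0:
        raise ValueError("factor_snr must be >= 0")
    rng = np.random.default_rng(seed)
    v = factor_variances(k_true)
    F = rng.standard_normal((n_words, k_true))
    F = F - F.mean(axis=0)
    Qf, _ = np.linalg.qr(F)
    F = Qf * np.sqrt(n_words * v)
    # orthonormal directions via QR of a square Gaussian, first k columns;
    # column k (orthogonal to all of them) carries the shared mean offset
    Q, _ = np.linalg.qr(rng.standard_normal((dims, dims)))
    L = Q[:, :k_true].T
    E = rng.standard_normal((n_words, dims))
    if factor_snr == 0:
        matrix = E
    else:
        noise_sd = np.sqrt(k_true / (dims * factor_snr))
        total_var = v.sum() + k_true / factor_snr
        mean_offset = EMBEDDING_MEAN_SCALE * np.sqrt(total_var) * Q[:, k_true]
        matrix = F @ L + noise_sd * E + mean_offset
    words = [f"w{i+1:04d}" for i in range(n_words)]
    truth = GroundTruth(factor_loadings=F, loading_directions=L, seed=seed)
    return EmbeddingSpace(words, matrix), truth


def plant_forward_model(
    truth: GroundTruth,
    n_sensors: int,
    planted_factors: tuple[int, ...] = DEFAULT_PLANTED,
    gain: float = 1.0,
    effect_window_ms: tuple[float, float] = DEFAULT_EFFECT_WINDOW_MS,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> GroundTruth:
    """Wire a subset of the planted factors into a dims x sensors mixing.

    The mixing is ``L[planted].T @ G`` with ``G`` a random planted x
    sensors pattern whose columns are normalized to ``gain``, so the
    noiseless peak signal at each sensor has standard deviation about
    ``gain * sqrt(mean planted factor variance)`` across items, and only
    the chosen factors reach the sensors.
    """
    if truth.loading_directions is None:
        raise ValueError("ground truth has no loading directions")
    if n_sensors < 1:
        raise ValueError("n_sensors must be positive")
    k_true = truth.loading_directions.shape[0]
    if any(not (0 <= f < k_true) for f in planted_factors):
        raise ValueError(f"planted factors must be in [0, {k_true})")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng([seed, 0x5E45])
    G = rng.standard_normal((len(planted_factors), n_sensors))
    G *= gain / np.linalg.norm(G, axis=0, keepdims=True)
    truth.mixing = truth.loading_directions[list(planted_factors)].T @ G
    truth.planted_factors = tuple(planted_factors)
    truth.effect_window_ms = tuple(effect_window_ms)
    truth.noise_sd = float(noise_sd)
    if gain != 0 and not np.any(truth.mixing):
        raise ValueError("requested encoding effect but mixing is all zero")
    return truth


def temporal_profile(
    times_ms: np.ndarray, window_ms: tuple[float, float]
) -> np.ndarray:
    """N400-like raised-cosine bump over the effect window.

    The Hann taper is sampled so that the window endpoints are interior
    points: every in-window sample carries signal, every sample outside
    the closed window is exactly zero, and the peak (1.0) sits at the
    window center.
    """
    t0, t1 = window_ms
    if not t0 < t1:
        raise ValueError("effect window must have t0 < t1")
    profile = np.zeros_like(times_ms, dtype=float)
    mask = (times_ms >= t0 - 1e-9) & (times_ms <= t1 + 1e-9)
    nw = int(mask.sum())
    if nw:
        taper = np.hanning(nw + 2)[1:-1]
        profile[mask] = taper / taper.max()
    return profile


def generate_erp(
    embeddings: EmbeddingSpace,
    truth: GroundTruth,
    n_sensors: int,
    t_start_ms: float = DEFAULT_EPOCH_MS[0],
    t_end_ms: float = DEFAULT_EPOCH_MS[1],
    rate_hz: float = DEFAULT_RATE_HZ,
):
    """Item-level ERPs from the planted linear spatiotemporal forward model.

    ``data[i, s, t] = (embedding_i . mixing[:, s]) * profile[t] + noise``
    with iid Gaussian sensor noise of sd ``truth.noise_sd``.  The default
    epoch is -100..920 ms at 200 Hz (205 samples, endpoints included).
    Subject-level variability is not simulated: the modeled object is the
    per-word subject-averaged ERP, and ``noise_sd`` is the residual noise
    that survives averaging.
    """
    from .encoding import ERPDataset  # local import avoids a cycle

    if not t_start_ms < t_end_ms:
        raise ValueError("t_start_ms must be < t_end_ms")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if truth.mixing is None:
        raise ValueError("ground truth has no mixing; call plant_forward_model")
    if truth.mixing.shape != (embeddings.dims, n_sensors):
        raise ValueError(
            f"mixing shape {truth.mixing.shape} does not match "
            f"(dims={embeddings.dims}, n_sensors={n_sensors})"
        )
    step = 1000.0 / rate_hz
    n_times = int(round((t_end_ms - t_start_ms) / step)) + 1
    times = t_start_ms + step * np.arange(n_times)
    profile = temporal_profile(times, truth.effect_window_ms)
    truth.temporal_profile = profile
    signal = (embeddings.matrix @ truth.mixing)[:, :, None] * profile[None, None, :]
    rng = np.random.default_rng([truth.seed, 0xE12])
    if truth.noise_sd > 0:
        signal = signal + truth.noise_sd * rng.standard_normal(signal.shape)
    return ERPDataset(
        words=list(embeddings.words),
        data=signal,
        rate_hz=rate_hz,
        t_start_ms=t_start_ms,
    )


def _spectral_bisect(D: np.ndarray, idx: list[int], words: list[str]):
    """Recursively split an index set into equal halves along the first
    classical-MDS coordinate of the sub-distance matrix."""
    from skbio import TreeNode

    if len(idx) == 1:
        return TreeNode(name=words[idx[0]])
    sub = D[np.ix_(idx, idx)]
    S = -0.5 * (sub - sub.mean(axis=0) - sub.mean(axis=1)[:, None] + sub.mean())
    _, vecs = np.linalg.eigh(S)
    order = np.argsort(vecs[:, -1], kind="stable")
    half = len(idx) // 2
    node = TreeNode()
    node.extend([
        _spectral_bisect(D, [idx[i] for i in order[:half]], words),
        _spectral_bisect(D, [idx[i] for i in order[half:]], words),
    ])
    return node


def generate_taxonomy(
    embeddings: EmbeddingSpace,
    fidelity: float = DEFAULT_TAXONOMY_FIDELITY,
    seed: int = 0,
) -> TaxonomyTree:
    """A rooted binary taxonomy that partially tracks embedding similarity.

    Built by recursive balanced spectral bisection of a blended pairwise
    distance: ``fidelity`` parts cosine distance (rescaled to [0, 1]) and
    ``1 - fidelity`` parts seeded random distance.  All leaves sit at
    (near-)equal depth, as in a category system, so the leaf-to-leaf edge
    count reflects the level at which two words separate — which is what
    makes path similarity informative about the blended metric.  fidelity
    1 gives a tree faithful to the vector space; fidelity 0 an unrelated
    one.
    """
    if embeddings.n_words == 0:
        raise ValueError("cannot build a taxonomy over an empty embedding")
    if not (0.0 <= fidelity <= 1.0):
        raise ValueError(f"fidelity must be in [0,1], got {fidelity}")
    n = embeddings.n_words
    cos_d = (1.0 - cosine_kernel(embeddings).values) / 2.0
    rng = np.random.default_rng(seed)
    rand = rng.uniform(size=(n, n))
    rand = (rand + rand.T) / 2.0
    np.fill_diagonal(rand, 0.0)
    blended = fidelity * cos_d + (1.0 - fidelity) * rand
    np.fill_diagonal(blended, 0.0)
    root = _spectral_bisect(blended, list(range(n)), embeddings.words)
    return TaxonomyTree(root)


def generate_covariates(
    embeddings: EmbeddingSpace,
    seed: int = 0,
    truth: GroundTruth | None = None,
    concreteness_corr: tuple[int, float] | None = CONCRETENESS_FACTOR_CORR,
    log_frequency_corr: tuple[int, float] | None = None,
) -> Covariates:
    """Per-word log frequency and concreteness.

    Log frequency is Normal(1.5, 1) — log10 counts per million for a noun
    sample; concreteness Normal(4.5, 1) on a 1–7 rating-like scale.  Either
    covariate can be correlated with a planted factor by a requested
    coefficient (concreteness tracks the leading factor by default, since
    concreteness is the classic first latent dimension of noun semantics);
    requires ``truth``.
    """
    if embeddings.n_words == 0:
        raise ValueError("empty embedding space")
    rng = np.random.default_rng(seed)
    n = embeddings.n_words

    def draw(base_mean, base_sd, corr):
        noise = rng.standard_normal(n)
        if corr is not None and truth is not None and truth.factor_loadings is not None:
            j, rho = corr
            f = truth.factor_loadings[:, j]
            f = (f - f.mean()) / f.std()
            raw = rho * f + np.sqrt(max(0.0, 1 - rho**2)) * noise
        else:
            raw = noise
        return base_mean + base_sd * raw

    log_freq = draw(1.5, 1.0, log_frequency_corr)
    concr = draw(4.5, 1.0, concreteness_corr)
    return Covariates(list(embeddings.words), log_freq, concr)


@dataclass
class SyntheticBundle:
    """A complete seeded fixture: inputs plus the planted ground truth."""

    space: EmbeddingSpace
    truth: GroundTruth
    taxonomy: TaxonomyTree
    covariates: Covariates
    erp: "object" = field(default=None)  # ERPDataset; type kept loose for import order


def simulate_bundle(
    preset: str | None = "german",
    seed: int = 0,
    *,
    n_words: int | None = None,
    n_sensors: int | None = None,
    dims: int = DEFAULT_DIMS,
    k_true: int = DEFAULT_K_TRUE,
    factor_snr: float = DEFAULT_FACTOR_SNR,
    planted_factors: tuple[int, ...] = DEFAULT_PLANTED,
    gain: float = 1.0,
    effect_window_ms: tuple[float, float] = DEFAULT_EFFECT_WINDOW_MS,
    noise_sd: float = DEFAULT_NOISE_SD,
    taxonomy_fidelity: float = DEFAULT_TAXONOMY_FIDELITY,
    t_start_ms: float = DEFAULT_EPOCH_MS[0],
    t_end_ms: float = DEFAULT_EPOCH_MS[1],
    rate_hz: float = DEFAULT_RATE_HZ,
) -> SyntheticBundle:
    """Generate the full fixture from one master seed.

    The master seed is expanded into independent child seeds for the
    embedding, forward model, taxonomy and covariates, so the whole bundle
    is reproduced bit-identically from ``(preset/overrides, seed)``.
    """
    shape = dict(PRESETS[preset]) if preset is not None else {}
    if n_words is not None:
        shape["n_words"] = n_words
    if n_sensors is not None:
        shape["n_sensors"] = n_sensors
    if "n_words" not in shape or "n_sensors" not in shape:
        raise ValueError("need a preset or explicit n_words and n_sensors")

    s_emb, s_mix, s_tax, s_cov = _child_seeds(seed, 4)
    space, truth = generate_embeddings(
        shape["n_words"], dims=dims, k_true=k_true, factor_snr=factor_snr, seed=s_emb
    )
    plant_forward_model(
        truth,
        shape["n_sensors"],
        planted_factors=planted_factors,
        gain=gain,
        effect_window_ms=effect_window_ms,
        noise_sd=noise_sd,
        seed=s_mix,
    )
    erp = generate_erp(
        space, truth, shape["n_sensors"],
        t_start_ms=t_start_ms, t_end_ms=t_end_ms, rate_hz=rate_hz,
    )
    taxonomy = generate_taxonomy(space, fidelity=taxonomy_fidelity, seed=s_tax)
    covariates = generate_covariates(space, seed=s_cov, truth=truth)
    return SyntheticBundle(space, truth, taxonomy, covariates, erp)
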