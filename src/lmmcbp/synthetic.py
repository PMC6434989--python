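"""Synthetic sentence corpora and single-trial ERP epochs with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a two-type sentence corpus (memory-encoded sentences with a
Recognition Point where predictability jumps from low to high, and common
sentences with moderate predictability throughout), cloze predictability
observed as binomial proportions over a panel of respondents, and
single-trial epochs built additively from

    amplitude(trial, e, t) = intercept(e, t)
                           + sum_k kernel_k(e, t) * x_k(trial)
                           + b_subject + b_word + noise(e, t)

with crossed random intercepts for subjects and word forms and residual
noise correlated across electrodes (exponential decay in sensor distance)
and smoothly correlated in time.  Every draw is a deterministic function
of the seed, and the full ground truth (templates, kernels, variance
parameters) is carried alongside the data for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .design import ModelSpec, build_design
from .preprocess import logit_predictability

# ---------------------------------------------------------------------------
# sensor layout


def make_layout(n_electrodes: int = 16, radius: float = 1.0) -> pd.DataFrame:
    """Deterministic quasi-uniform cap layout (Fibonacci spiral on a
    spherical cap), labels ``E01``… with x, y, z coordinates."""
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    golden = (1 + 5**0.5) / 2
    k = np.arange(n_electrodes)
    # polar angle limited to the upper cap (~100 degrees aperture)
    cos_theta = 1.0 - 1.15 * (k + 0.5) / n_electrodes
    theta = np.arccos(np.clip(cos_theta, -1, 1))
    phi = 2 * np.pi * k / golden
    width = max(2, len(str(n_electrodes)))
    return pd.DataFrame(
        {
            "label": [f"E{i + 1:0{width}d}" for i in k],
            "x": radius * np.sin(theta) * np.cos(phi),
            "y": radius * np.sin(theta) * np.sin(phi),
            "z": radius * np.cos(theta),
        }
    )


def centro_parietal_electrodes(layout: pd.DataFrame, fraction: float = 0.3) -> list[str]:
    """Electrodes closest to a centro-parietal reference point (posterior
    midline, slightly behind the vertex)."""
    ref = np.array([0.0, -0.45, 0.9])
    ref = ref / np.linalg.norm(ref)
    coords = layout[["x", "y", "z"]].to_numpy()
    d = np.linalg.norm(coords - ref * np.linalg.norm(coords, axis=1, keepdims=True), axis=1)
    n_pick = max(2, int(round(fraction * len(layout))))
    order = np.argsort(d, kind="stable")[:n_pick]
    return layout["label"].iloc[np.sort(order)].tolist()


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the generator injects, serialisable for recovery tests."""

    times: np.ndarray                      # ms
    electrodes: list[str]
    intercept: np.ndarray                  # (E, T) ERP template
    kernels: dict[str, np.ndarray]         # coefficient name -> (E, T)
    sd_subject: float = 2.0
    sd_word: float = 1.5
    sd_noise: float = 8.0
    spatial_length_scale: float = 0.6
    temporal_length_scale_ms: float = 40.0

    def __post_init__(self) -> None:
        grid = (len(self.electrodes), self.times.size)
        if self.intercept.shape != grid:
            raise ValueError("intercept template shape mismatch")
        for name, kern in self.kernels.items():
            if kern.shape != grid:
                raise ValueError(f"kernel {name!r} shape mismatch")
        if min(self.sd_subject, self.sd_word, self.sd_noise) < 0:
            raise ValueError("standard deviations must be >= 0")

    def zeroed(self, keep_intercept: bool = True) -> "GroundTruth":
        """Copy with every fixed-effect kernel set to zero (null truth)."""
        grid_zero = {k: np.zeros_like(v) for k, v in self.kernels.items()}
        return GroundTruth(
            times=self.times.copy(),
            electrodes=list(self.electrodes),
            intercept=self.intercept.copy() if keep_intercept else np.zeros_like(self.intercept),
            kernels=grid_zero,
            sd_subject=self.sd_subject,
            sd_word=self.sd_word,
            sd_noise=self.sd_noise,
            spatial_length_scale=self.spatial_length_scale,
            temporal_length_scale_ms=self.temporal_length_scale_ms,
        )

    def to_json(self, path) -> None:
        payload = {
            "times": self.times.tolist(),
            "electrodes": self.electrodes,
            "intercept": self.intercept.tolist(),
            "kernels": {k: v.tolist() for k, v in self.kernels.items()},
            "sd_subject": self.sd_subject,
            "sd_word": self.sd_word,
            "sd_noise": self.sd_noise,
            "spatial_length_scale": self.spatial_length_scale,
            "temporal_length_scale_ms": self.temporal_length_scale_ms,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            times=np.array(d["times"], dtype=float),
            electrodes=list(d["electrodes"]),
            intercept=np.array(d["intercept"], dtype=float),
            kernels={k: np.array(v, dtype=float) for k, v in d["kernels"].items()},
            sd_subject=d["sd_subject"],
            sd_word=d["sd_word"],
            sd_noise=d["sd_noise"],
            spatial_length_scale=d["spatial_length_scale"],
            temporal_length_scale_ms=d["temporal_length_scale_ms"],
        )


def _gaussian_bump(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def _spatial_profile(layout: pd.DataFrame, focus: list[str], sharpness: float = 0.5) -> np.ndarray:
    """Per-electrode weight decaying with distance from the focus centroid."""
    coords = layout[["x", "y", "z"]].to_numpy()
    idx = layout.index[layout["label"].isin(focus)]
    centroid = coords[idx].mean(axis=0)
    d = np.linalg.norm(coords - centroid, axis=1)
    return np.exp(-0.5 * (d / sharpness) ** 2)


def default_truth(
    layout: pd.DataFrame,
    n_times: int = 32,
    t_start_ms: float = -100.0,
    dt_ms: float = 25.0,
    pred_common_amplitude: float = 1.5,
    pred_memory_amplitude: float = 0.0,
    position_amplitude: float = 0.4,
    frequency_amplitude: float = 0.0,
    sd_subject: float = 2.0,
    sd_word: float = 1.5,
    sd_noise: float = 8.0,
) -> GroundTruth:
    """Reference ground truth emulating the expected effect geometry.

    The predictability kernel for common sentences lives on the
    centro-parietal electrodes in the N400 interval (positive: higher
    predictability pulls the window amplitude up, i.e. attenuates the
    N400); by default memory-encoded sentences carry *no* predictability
    effect.  The word-position kernel is a spatially widespread sustained
    drift switching on near 170 ms.  Amplitudes are μV per unit of the
    (centered) covariate.
    """
    times = t_start_ms + dt_ms * np.arange(n_times)
    electrodes = layout["label"].tolist()
    E, T = len(electrodes), n_times

    n1 = -2.0 * _gaussian_bump(times, 110.0, 30.0)
    p2 = 2.2 * _gaussian_bump(times, 220.0, 45.0)
    slow = 1.0 * _gaussian_bump(times, 450.0, 150.0)
    intercept = np.tile(n1 + p2 + slow, (E, 1))

    cp = centro_parietal_electrodes(layout)
    n400_time = _gaussian_bump(times, 375.0, 55.0)
    n400_time[(times < 280.0) | (times > 470.0)] = 0.0
    pred_space = _spatial_profile(layout, cp, sharpness=0.55)
    pred_kernel = np.outer(pred_space, n400_time)

    onset = 1.0 / (1.0 + np.exp(-(times - 170.0) / 25.0))
    pos_space = 0.6 + 0.4 * _spatial_profile(layout, electrodes, sharpness=1.5)
    pos_kernel = np.outer(pos_space, onset)

    kernels = {
        "predictability:common": pred_common_amplitude * pred_kernel,
        "predictability:memory_encoded": pred_memory_amplitude * pred_kernel,
        "position:common": position_amplitude * pos_kernel,
        "position:memory_encoded": position_amplitude * pos_kernel,
        "frequency": frequency_amplitude * np.outer(pred_space, n400_time),
    }
    return GroundTruth(
        times=times,
        electrodes=electrodes,
        intercept=intercept,
        kernels=kernels,
        sd_subject=sd_subject,
        sd_word=sd_word,
        sd_noise=sd_noise,
    )


# ---------------------------------------------------------------------------
# corpus


_POS_TAGS = np.array(["noun", "verb", "adjective", "determiner", "preposition"])
_POS_PROBS = np.array([0.34, 0.20, 0.14, 0.17, 0.15])


@dataclass
class SimulatedCorpus:
    """Word-level table plus per-sentence metadata and generation settings."""

    words: pd.DataFrame        # one row per word slot
    sentences: pd.DataFrame    # one row per sentence (type, length, rp_position)
    n_cloze_respondents: int
    seed: int

    @property
    def unique_word_fraction(self) -> float:
        counts = self.words["word_form"].value_counts()
        return float((counts == 1).sum() / len(counts))


def simulate_corpus(
    n_memory: int = 50,
    n_common: int = 80,
    n_cloze_respondents: int = 18,
    seed: int = 0,
    min_words: int = 5,
    max_words: int = 12,
    repeated_word_fraction: float = 0.2,
    n_repeated_pool: int = 30,
) -> SimulatedCorpus:
    """Generate a two-type sentence corpus with cloze predictability.

    Memory-encoded sentences carry a low latent predictability before the
    Recognition Point and a high one from the RP on; common sentences sit
    at a moderate level with a mild upward position trend.  Observed
    predictability is a binomial proportion over ``n_cloze_respondents``
    (so raw values of exactly 0 and 1 occur, as in a real cloze norming).
    Word forms are mostly corpus-unique, with a configurable repetition
    tail drawn from a small pool of frequent fillers; the Recognition
    Point is recorded as the word with the maximal predictability jump.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 101])
    pool = [f"filler{j:02d}" for j in range(n_repeated_pool)]
    pool_len = rng.integers(2, 9, size=n_repeated_pool)
    freq_by_form: dict[str, float] = {}
    counter = 0
    w_rows, s_rows = [], []
    for s_i in range(n_memory + n_common):
        stype = "memory_encoded" if s_i < n_memory else "common"
        sid = f"{'m' if stype == 'memory_encoded' else 'c'}{s_i:03d}"
        length = int(rng.integers(min_words, max_words + 1))
        rp_pos = int(rng.integers(2, length)) if stype == "memory_encoded" else -1
        latent = np.empty(length)
        for pos in range(1, length + 1):
            if stype == "memory_encoded":
                latent[pos - 1] = 0.85 if pos >= rp_pos else 0.15
            else:
                latent[pos - 1] = min(0.35 + 0.015 * (pos - 1), 0.6)
        raw = rng.binomial(n_cloze_respondents, latent) / n_cloze_respondents
        jumps = np.diff(raw)
        observed_rp = int(np.argmax(jumps)) + 2 if stype == "memory_encoded" else -1
        for pos in range(1, length + 1):
            use_pool = (
                repeated_word_fraction > 0
                and rng.random() < repeated_word_fraction
            )
            if use_pool:
                j = int(rng.integers(n_repeated_pool))
                form, length_chars = pool[j], int(pool_len[j])
            else:
                form, length_chars = f"w{counter:05d}", int(rng.integers(2, 11))
                counter += 1
            if form not in freq_by_form:
                freq_by_form[form] = float(rng.normal(3.0, 1.0))
            w_rows.append(
                {
                    "sentence_id": sid,
                    "sentence_type": stype,
                    "position": pos,
                    "word_form": form,
                    "word_length": length_chars,
                    "pos_tag": str(rng.choice(_POS_TAGS, p=_POS_PROBS))
                    if pos > 1
                    else "determiner",
                    "predictability_raw": float(raw[pos - 1]),
                    "frequency": freq_by_form[form],
                    "rp_relative_position": (pos - observed_rp)
                    if stype == "memory_encoded"
                    else np.nan,
                }
            )
        s_rows.append(
            {
                "sentence_id": sid,
                "sentence_type": stype,
                "length": length,
                "rp_position": observed_rp if stype == "memory_encoded" else np.nan,
            }
        )
    words = pd.DataFrame(w_rows)
    words["predictability"] = logit_predictability(
        words["predictability_raw"].to_numpy(), n_cloze_respondents
    )
    return SimulatedCorpus(
        words=words,
        sentences=pd.DataFrame(s_rows),
        n_cloze_respondents=n_cloze_respondents,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# epochs


def _correlation_cholesky(dist: np.ndarray, length_scale: float) -> np.ndarray:
    corr = np.exp(-dist / max(length_scale, 1e-12))
    corr += 1e-8 * np.eye(dist.shape[0])
    return np.linalg.cholesky(corr)


def simulate_epochs(
    corpus: SimulatedCorpus,
    truth: GroundTruth,
    n_subjects: int = 25,
    layout: pd.DataFrame | None = None,
    seed: int = 0,
    spec: ModelSpec | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Cross every subject with every corpus word and synthesise epochs.

    Fixed-effect contributions use exactly the analysis model's nested
    per-type slope coding (via :func:`build_design` on the same covariate
    table), so recovery tests compare estimate maps against kernels in
    the same basis.  Random draws (subject and word intercepts, residual
    noise) happen before and independently of the kernel values, which
    makes the generator additive: for a fixed seed the output with two
    kernels equals the sum of the single-kernel outputs minus one
    intercept-only output, exactly.
    """
    if layout is not None and layout["label"].tolist() != truth.electrodes:
        raise ValueError("layout electrodes do not match ground truth")
    if spec is None:
        spec = ModelSpec()
    rng = np.random.default_rng([int(seed) % (2**31), 202])
    words = corpus.words
    n_words = len(words)
    subjects = [f"S{j + 1:02d}" for j in range(n_subjects)]

    table = pd.concat(
        [words.assign(subject_id=s) for s in subjects], ignore_index=True
    )
    table.insert(0, "trial_id", np.arange(len(table)))
    n_trials = len(table)
    E, T = len(truth.electrodes), truth.times.size

    # random draws in fixed order, independent of kernel values
    b_subj = rng.normal(0.0, truth.sd_subject, size=n_subjects)
    forms = sorted(words["word_form"].unique().tolist())
    b_word = dict(zip(forms, rng.normal(0.0, truth.sd_word, size=len(forms))))
    noise_white = rng.standard_normal((n_trials, E, T))

    if layout is None:
        coords = None
    else:
        coords = layout[["x", "y", "z"]].to_numpy()
    if coords is not None and truth.spatial_length_scale > 0:
        from scipy.spatial.distance import pdist, squareform

        Ls = _correlation_cholesky(
            squareform(pdist(coords)), truth.spatial_length_scale
        )
    else:
        Ls = np.eye(E)
    tdist = np.abs(truth.times[:, None] - truth.times[None, :])
    Lt = (
        _correlation_cholesky(tdist, truth.temporal_length_scale_ms)
        if truth.temporal_length_scale_ms > 0
        else np.eye(T)
    )
    noise = truth.sd_noise * np.einsum("ef,nfg,tg->net", Ls, noise_white, Lt)

    design = build_design(table, spec)
    signal = np.tile(truth.intercept, (n_trials, 1, 1))
    name_to_col = {n: i for i, n in enumerate(design.coef_names)}
    for kname, kernel in truth.kernels.items():
        if kname not in name_to_col:
            raise KeyError(
                f"kernel {kname!r} has no matching design coefficient "
                f"{design.coef_names}"
            )
        x = design.X[:, name_to_col[kname]]
        signal += x[:, None, None] * kernel[None, :, :]

    subj_effect = table["subject_id"].map(dict(zip(subjects, b_subj))).to_numpy()
    word_effect = table["word_form"].map(b_word).to_numpy()
    amplitudes = signal + (subj_effect + word_effect)[:, None, None] + noise

    epochs = EpochSet(
        amplitudes=amplitudes,
        times=truth.times.copy(),
        electrodes=list(truth.electrodes),
        trial_ids=table["trial_id"].to_numpy(),
    )
    return epochs, table


def simulate_null(
    corpus: SimulatedCorpus,
    truth: GroundTruth,
    n_subjects: int = 25,
    layout: pd.DataFrame | None = None,
    seed: int = 0,
    keep_intercept: bool = False,
    spec: ModelSpec | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Epochs with every fixed-effect kernel zeroed.

    Random intercepts and correlated noise are retained, so the null data
    keep exactly the crossed random-factor structure the permutation
    schemes must respect.
    """
    return simulate_epochs(
        corpus,
        truth.zeroed(keep_intercept=keep_intercept),
        n_subjects=n_subjects,
        layout=layout,
        seed=seed,
        spec=spec,
    )
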