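"""Resting-state preprocessing and HMM state partitioning.

Continuous sensor data are band-passed 1-90 Hz with a 48-52 Hz notch
(both zero-phase 4th-order Butterworth), resampled to 250 Hz, reduced by
PCA to standardized component scores, and segmented by a Gaussian-
observation hidden Markov model. The Viterbi statepath is used to tag
non-overlapping 200 ms epochs by their modal state, yielding one dataset
of quasi-stationary epochs per network state; the most-occupied states
are taken forward for inversion.

The observation model is a full-covariance Gaussian per state on the PCA
scores: the partitioning role only requires segments that are self-similar
in sensor covariance, not a specific spectral model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import h5py
import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import signal as sps

from .synthgen import SensorRecording

__all__ = [
    "StatePath",
    "StateDataset",
    "preprocess",
    "pca_reduce",
    "fit_hmm",
    "epoch_modal",
    "partition_states",
    "dominant_states",
    "state_sensor_map",
    "match_states",
]

TARGET_FS = 250.0
BAND = (1.0, 90.0)
NOTCH = (48.0, 52.0)


@dataclass
class StatePath:
    """Per-sample most-probable state indices (1..K)."""

    states: np.ndarray  # (T,) int, 1-based
    K: int
    fs: float

    def validate(self) -> None:
        if self.states.min() < 1 or self.states.max() > self.K:
            raise ValueError("state indices must lie in 1..K")

    def save_tsv(self, path) -> None:
        pd.DataFrame({"state": self.states}).to_csv(
            path, sep="\t", index=False, header=[f"state_fs={self.fs}"]
        )

    @classmethod
    def load_tsv(cls, path) -> "StatePath":
        df = pd.read_csv(path, sep="\t")
        fs = float(df.columns[0].split("=")[1])
        states = df.iloc[:, 0].to_numpy(int)
        return cls(states=states, K=int(states.max()), fs=fs)


@dataclass
class StateDataset:
    """Epochs (E x C x S) whose modal statepath state is ``state_id``."""

    state_id: int
    epochs: np.ndarray  # (E, C, S)
    fs: float
    labels: list

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("epochs", data=self.epochs)
            f.create_dataset(
                "labels", data=np.array(self.labels, dtype=h5py.string_dtype())
            )
            f.attrs["state_id"] = self.state_id
            f.attrs["fs"] = self.fs

    @classmethod
    def load_h5(cls, path) -> "StateDataset":
        with h5py.File(path, "r") as f:
            return cls(
                state_id=int(f.attrs["state_id"]),
                epochs=f["epochs"][()],
                fs=float(f.attrs["fs"]),
                labels=[
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["labels"][()]
                ],
            )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(rec: SensorRecording, target_fs: float = TARGET_FS) -> SensorRecording:
    """Band-pass 1-90 Hz, notch 48-52 Hz (zero-phase), resample to 250 Hz."""
    if rec.fs < target_fs:
        raise ValueError(f"sampling rate {rec.fs} below resampling target {target_fs}")
    if rec.fs <= 2 * BAND[1]:
        raise ValueError(f"sampling rate {rec.fs} too low for a {BAND[1]} Hz band edge")
    sos_bp = sps.butter(4, BAND, btype="bandpass", fs=rec.fs, output="sos")
    sos_bs = sps.butter(4, NOTCH, btype="bandstop", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos_bp, rec.data, axis=1)
    x = sps.sosfiltfilt(sos_bs, x, axis=1)
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    truth = rec.state_truth
    if truth is not None:
        # decimate ground truth by nearest-sample lookup on the new grid
        idx = np.minimum(
            (np.arange(x.shape[1]) * rec.fs / target_fs).round().astype(int),
            len(truth) - 1,
        )
        truth = truth[idx]
    return replace(rec, data=x, fs=float(target_fs), state_truth=truth)


def pca_reduce(rec: SensorRecording, n_comp: int = 40) -> np.ndarray:
    """Top principal-component scores, standardized to zero mean, unit variance.

    Returns an (n_comp, T) array. Components with (numerically) zero
    variance are dropped with a warning, so fewer than ``n_comp`` rows may
    be returned on rank-deficient data.
    """
    from sklearn.decomposition import PCA

    if n_comp > rec.n_channels:
        raise ValueError("n_comp cannot exceed channel count")
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(rec.data.T)  # (T, n_comp)
    sd = scores.std(axis=0)
    keep = sd > 1e-12 * max(sd.max(), 1e-300)
    if not keep.all():
        warnings.warn(
            f"input rank below {n_comp}: dropped {int((~keep).sum())} "
            "zero-variance components"
        )
        scores = scores[:, keep]
        sd = sd[keep]
    scores = (scores - scores.mean(axis=0)) / sd
    return scores.T


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------


def fit_hmm(
    components: np.ndarray,
    K: int = 8,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
):
    """Gaussian-observation HMM (full covariance) with Viterbi statepath.

    EM runs until the relative log-likelihood improvement drops below
    ``tol``; ``n_restarts`` random initializations are tried and the best
    likelihood kept. Deterministic for fixed seed. Returns
    ``(model, StatePath)``; the statepath is 1-based.
    """
    X = np.asarray(components, float).T  # (T, n_comp)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        model = GaussianHMM(n_components=1, covariance_type="full", n_iter=1)
        model.fit(X)
        path = np.ones(len(X), dtype=int)
        return model, StatePath(states=path, K=1, fs=np.nan)
    best, best_ll = None, -np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        model = GaussianHMM(
            n_components=K,
            covariance_type="full",
            n_iter=max_iter,
            tol=tol * abs(len(X)),
            random_state=int(rng.integers(2**31 - 1)),
            min_covar=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X)
                ll = model.score(X)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if ll > best_ll:
            best, best_ll = model, ll
    if best is None:
        raise RuntimeError("all HMM restarts failed (degenerate covariance)")
    _, viterbi = best.decode(X, algorithm="viterbi")
    return best, StatePath(states=viterbi + 1, K=K, fs=np.nan)


def match_states(path: np.ndarray, truth: np.ndarray, K: int) -> np.ndarray:
    """Relabel ``path`` to best match ``truth`` (Hungarian on the confusion).

    Both arrays are 1-based. Returns the relabelled path; used to compare
    HMM fits up to state-label permutation.
    """
    from scipy.optimize import linear_sum_assignment

    confusion = np.zeros((K, K))
    for a, b in zip(path, truth):
        confusion[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-confusion)
    mapping = dict(zip(rows, cols))
    return np.array([mapping[s - 1] + 1 for s in path])


# ---------------------------------------------------------------------------
# Epoching and partitioning
# ---------------------------------------------------------------------------


def epoch_modal(rec: SensorRecording, path: StatePath, epoch_ms: float = 200.0):
    """Non-overlapping epochs tagged with the modal statepath state.

    Epoch length is ``round(epoch_ms*fs/1000)`` samples; the trailing
    partial epoch is discarded. Modal-state ties resolve to the lower
    state index. Returns a list of ``(epoch (C, S), modal_state)`` pairs.
    """
    if len(path.states) != rec.n_samples:
        raise ValueError("statepath must align with the recording")
    S = int(round(epoch_ms * rec.fs / 1000.0))
    if S > rec.n_samples:
        raise ValueError("epoch longer than recording")
    n_ep = rec.n_samples // S
    out = []
    for e in range(n_ep):
        seg = slice(e * S, (e + 1) * S)
        counts = np.bincount(path.states[seg], minlength=path.K + 1)
        modal = int(np.argmax(counts))  # argmax takes the lowest index on ties
        out.append((rec.data[:, seg], modal))
    return out


def partition_states(tagged_epochs, K: int, fs: float, labels) -> list:
    """One StateDataset per state 1..K; total epoch count is conserved.

    States with no epochs yield an empty dataset, not an error.
    """
    by_state = {k: [] for k in range(1, K + 1)}
    for ep, tag in tagged_epochs:
        if not 1 <= tag <= K:
            raise ValueError(f"epoch tag {tag} outside 1..{K}")
        by_state[tag].append(ep)
    datasets = []
    for k in range(1, K + 1):
        eps = (
            np.stack(by_state[k])
            if by_state[k]
            else np.empty((0,) + tagged_epochs[0][0].shape)
        )
        datasets.append(StateDataset(state_id=k, epochs=eps, fs=fs, labels=list(labels)))
    return datasets


def dominant_states(datasets, n: int = 4) -> list:
    """The n datasets with most epochs (most time in state); ties -> lower id."""
    nonempty = [d for d in datasets if d.n_epochs > 0]
    if len(nonempty) < n:
        warnings.warn(
            f"only {len(nonempty)} nonempty state datasets (requested {n})"
        )
        n = len(nonempty)
    order = sorted(nonempty, key=lambda d: (-d.n_epochs, d.state_id))
    return order[:n]


def state_sensor_map(rec: SensorRecording, path: StatePath, state: int) -> np.ndarray:
    """Per-channel Pearson correlation of the state indicator with the
    channel amplitude envelope (|analytic signal|)."""
    indicator = (path.states == state).astype(float)
    if indicator.sum() == 0:
        raise ValueError(f"state {state} never visited: map undefined")
    if indicator.std() == 0:
        raise ValueError("state indicator is constant: correlation undefined")
    env = np.abs(sps.hilbert(rec.data, axis=1))
    ind = indicator - indicator.mean()
    env_c = env - env.mean(axis=1, keepdims=True)
    num = env_c @ ind
    den = np.linalg.norm(env_c, axis=1) * np.linalg.norm(ind)
    with np.errstate(invalid="ignore"):
        return num / den
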