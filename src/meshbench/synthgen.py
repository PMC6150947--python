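"""Synthetic cortices, sensor arrays and state-switching MEG-like recordings.

The generator emulates the statistical structure the benchmark assumes:
a closed genus-0 "cortex" with mesh-scale folds, point magnetometers on an
outer spherical cap, and source activity that switches between a small
number of spatially distinct network states on a 100-200 ms timescale,
optionally degraded by additive sensor white noise at a controlled SNR.

Two data-degradation controls are provided: power-calibrated white-noise
injection (``add_noise_db``) and channel-label shuffling
(``shuffle_channels``), which destroys the correspondence between channel
labels/positions and the data rows while leaving the multiset of time
series untouched.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import trimesh
from scipy import signal

__all__ = [
    "CorticalMesh",
    "SensorArray",
    "SensorRecording",
    "SimConfig",
    "gen_mesh",
    "gen_sensor_array",
    "simulate_recording",
    "add_noise_db",
    "shuffle_channels",
]


def _rng(seed: int, op: str) -> np.random.Generator:
    """Per-operation RNG: one integer seed, stream split by operation name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(op.encode())])
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CorticalMesh:
    """Closed triangulated surface with outward unit vertex normals (mm).

    Vertex positions are in millimetres; faces are 0-based index triples
    with consistent outward winding. ``normals`` are area-weighted vertex
    normals, unit length, oriented away from the component centroid.
    """

    vertices: np.ndarray  # (N, 3) float64, mm
    faces: np.ndarray  # (M, 3) int
    normals: np.ndarray  # (N, 3) float64, unit

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def euler_characteristic(self) -> int:
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return self.n_vertices - len(edges) + len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def with_vertices(self, vertices: np.ndarray) -> "CorticalMesh":
        """Same topology, new vertex positions; normals recomputed."""
        return mesh_from_arrays(vertices, self.faces)

    # -- I/O ---------------------------------------------------------------

    def save_gifti(self, path) -> None:
        import nibabel as nib

        darrays = [
            nib.gifti.GiftiDataArray(
                self.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                self.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
        nib.gifti.GiftiImage(darrays=darrays).to_filename(str(path))

    @classmethod
    def load_gifti(cls, path) -> "CorticalMesh":
        import nibabel as nib

        img = nib.load(str(path))
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return mesh_from_arrays(np.asarray(verts, float), np.asarray(faces, int))

    def save_obj(self, path) -> None:
        self.as_trimesh().export(str(path), file_type="obj")

    @classmethod
    def load_obj(cls, path) -> "CorticalMesh":
        tm = trimesh.load(str(path), file_type="obj", process=False)
        return mesh_from_arrays(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))


@dataclass
class SensorArray:
    """Point-magnetometer array outside a spherical volume conductor."""

    labels: list
    positions: np.ndarray  # (C, 3) mm
    orientations: np.ndarray  # (C, 3) unit pickup directions
    conductor_center: np.ndarray  # (3,) mm
    conductor_radius: float  # mm

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")
        d = np.linalg.norm(self.positions - self.conductor_center, axis=1)
        if np.any(d <= self.conductor_radius):
            raise ValueError("all sensors must lie strictly outside the conductor")
        if not np.allclose(np.linalg.norm(self.orientations, axis=1), 1.0, atol=1e-9):
            raise ValueError("orientations must be unit length")

    def save_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path, conductor_center=(0.0, 0.0, 0.0), conductor_radius=95.0):
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=list(df["label"]),
            positions=df[["x", "y", "z"]].to_numpy(float),
            orientations=df[["ox", "oy", "oz"]].to_numpy(float),
            conductor_center=np.asarray(conductor_center, float),
            conductor_radius=float(conductor_radius),
        )


@dataclass
class SensorRecording:
    """Multichannel sensor time series (channels x samples)."""

    data: np.ndarray  # (C, T)
    fs: float  # Hz
    labels: list
    state_truth: Optional[np.ndarray] = None  # (T,) 1-based state index
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if len(self.labels) != self.n_channels:
            raise ValueError("label count must equal channel count")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset(
                "labels", data=np.array(self.labels, dtype=h5py.string_dtype())
            )
            f.attrs["fs"] = self.fs
            for k in ("snr_db", "seed"):
                if k in self.meta and self.meta[k] is not None:
                    f.attrs[k] = self.meta[k]
            if self.state_truth is not None:
                f.create_dataset("state_truth", data=self.state_truth)

    @classmethod
    def load_h5(cls, path) -> "SensorRecording":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            labels = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]
            ]
            fs = float(f.attrs["fs"])
            truth = f["state_truth"][()] if "state_truth" in f else None
            meta = {k: f.attrs[k] for k in ("snr_db", "seed") if k in f.attrs}
        return cls(data=data, fs=fs, labels=labels, state_truth=truth, meta=meta)


@dataclass
class SimConfig:
    """Conditions for one synthetic resting-state-like recording.

    Defaults mirror a 10-minute resting block: eight network states
    switching on a ~200 ms timescale, a few focal cortical generators per
    state, sampled at 1200 Hz.
    """

    n_states: int = 8
    state_dwell_ms: float = 200.0
    sources_per_state: int = 3
    source_amplitude: float = 20.0  # nAm
    snr_db: Optional[float] = 5.0
    duration_s: float = 600.0
    fs: float = 1200.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.state_dwell_ms > 0:
            raise ValueError("state_dwell_ms must be positive")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def mesh_from_arrays(vertices: np.ndarray, faces: np.ndarray) -> CorticalMesh:
    """Build a CorticalMesh, recomputing outward unit vertex normals."""
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    normals = np.array(tm.vertex_normals, dtype=float)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # Enforce outward orientation relative to the component centroid.
    centroid = vertices.mean(axis=0)
    outward = np.einsum("ij,ij->i", normals, vertices - centroid)
    if np.mean(outward > 0) < 0.5:
        normals = -normals
    return CorticalMesh(
        vertices=np.asarray(vertices, float),
        faces=np.asarray(faces, int),
        normals=normals,
    )


def _icosphere_for(n_vertices: int, radius: float) -> trimesh.Trimesh:
    # icosphere vertex counts: 12, 42, 162, 642, 2562, ... (10*4^s + 2)
    subdiv = 0
    while 10 * 4**subdiv + 2 < n_vertices and subdiv < 7:
        subdiv += 1
    return trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)


def _real_sph_harm_field(
    unit_dirs: np.ndarray, degree: int, rng: np.random.Generator
) -> np.ndarray:
    """Random band-limited "folding" field, unit RMS over the sampled vertices.

    Harmonic content spans degrees 2..``degree`` with per-coefficient
    amplitude proportional to l, so the finest folds (scale ~ ``degree``)
    dominate while coarser shape variation is present — a multi-scale
    pattern, as on a real cortex, rather than a single-wavelength ripple.
    """
    from .meshlib import real_sph_harm_basis

    l_lo = min(2, degree)
    basis = real_sph_harm_basis(unit_dirs, l_min=l_lo, l_max=degree)
    degs = np.concatenate(
        [np.full(2 * l + 1, l) for l in range(l_lo, degree + 1)]
    )
    coeffs = rng.standard_normal(basis.shape[1]) * (degs / degree)
    f = basis @ coeffs
    return f / np.sqrt(np.mean(f**2))


def gen_mesh(
    n_vertices: int = 642,
    fold_amplitude: float = 5.0,
    fold_frequency: int = 12,
    radius: float = 70.0,
    seed: int = 0,
    n_components: int = 1,
) -> CorticalMesh:
    """Closed genus-0 toy cortex: icosphere with harmonic radial "folds".

    The sphere radius is perturbed by ``fold_amplitude`` times a unit-RMS
    random field built from degree-``fold_frequency`` spherical harmonics,
    giving folds of a controlled spatial scale. ``n_components=2`` places a
    second, independently folded ovoid alongside the first (a stand-in for
    two hemispheres); each component is a closed genus-0 surface.

    Parameters are in millimetres. Deterministic for fixed seed.
    """
    if n_vertices < 12:
        raise ValueError("n_vertices must be >= 12")
    if not radius > 0:
        raise ValueError("radius must be positive")
    if fold_amplitude < 0:
        raise ValueError("fold_amplitude must be non-negative")
    if fold_frequency < 1:
        raise ValueError("fold_frequency must be >= 1")

    rng = _rng(seed, "gen_mesh")
    all_verts, all_faces = [], []
    offset = 0
    for comp in range(max(1, int(n_components))):
        sphere = _icosphere_for(n_vertices, radius)
        verts = np.array(sphere.vertices, dtype=float)
        unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        if fold_amplitude > 0:
            perturb = _real_sph_harm_field(unit, fold_frequency, rng)
            r = radius + fold_amplitude * perturb
        else:
            r = np.full(len(unit), radius)
        verts = unit * r[:, None]
        verts[:, 0] += comp * 2.5 * radius  # place second ovoid alongside
        all_verts.append(verts)
        all_faces.append(np.array(sphere.faces, dtype=int) + offset)
        offset += len(verts)
    return mesh_from_arrays(np.vstack(all_verts), np.vstack(all_faces))


def gen_sensor_array(
    n_channels: int = 272,
    cap_radius: float = 120.0,
    conductor_radius: float = 95.0,
    seed: int = 0,
    cap_fraction: float = 0.65,
) -> SensorArray:
    """Quasi-uniform magnetometers on the upper cap of a sphere.

    Channels are laid out by a golden-angle (Fibonacci) spiral covering the
    upper ``cap_fraction`` of the sphere's surface, with radial pickup
    orientations. A small seeded tangential jitter breaks the exact lattice.
    """
    if not cap_radius > conductor_radius:
        raise ValueError("cap_radius must exceed conductor_radius")
    if not conductor_radius > 0:
        raise ValueError("conductor_radius must be positive")
    rng = _rng(seed, "gen_sensor_array")
    i = np.arange(n_channels)
    # uniform in z over the cap [1 - 2*cap_fraction, 1]
    z = 1.0 - (i + 0.5) / n_channels * (2.0 * cap_fraction)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts = pts + 0.002 * rng.standard_normal(pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    positions = pts * cap_radius
    arr = SensorArray(
        labels=[f"MEG{k + 1:04d}" for k in range(n_channels)],
        positions=positions,
        orientations=pts.copy(),
        conductor_center=np.zeros(3),
        conductor_radius=float(conductor_radius),
    )
    arr.validate()
    return arr


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------


def _markov_statepath(
    n_states: int, dwell_samples: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov chain with geometric dwell of given mean (1-based)."""
    stay = max(0.0, 1.0 - 1.0 / dwell_samples) if n_states > 1 else 1.0
    states = np.empty(n_samples, dtype=int)
    s = int(rng.integers(n_states))
    u = rng.random(n_samples)
    jumps = rng.integers(1, n_states, size=n_samples) if n_states > 1 else None
    for t in range(n_samples):
        if n_states > 1 and u[t] >= stay:
            s = (s + jumps[t]) % n_states
        states[t] = s
    return states + 1


def _bandlimited_courses(
    n_sources: int, n_samples: int, fs: float, rng: np.random.Generator,
    band=(1.0, 90.0),
) -> np.ndarray:
    """Unit-variance Gaussian processes band-passed to the analysis band."""
    x = rng.standard_normal((n_sources, n_samples))
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def simulate_recording(
    mesh: CorticalMesh,
    sensors: SensorArray,
    cfg: SimConfig,
    gain: "np.ndarray | object",
) -> SensorRecording:
    """State-switching source activity projected to the sensors.

    A first-order Markov state sequence with mean dwell ``cfg.state_dwell_ms``
    selects which network state is active; each state owns
    ``cfg.sources_per_state`` fixed vertices (disjoint across states) whose
    band-limited (1-90 Hz) unit-variance Gaussian-process time courses, scaled
    by ``cfg.source_amplitude`` (nAm), are projected through the lead fields
    while the state is active. Ground-truth state indices are recorded.
    Sensor white noise is added per ``cfg.snr_db`` (None = noiseless).
    """
    cfg.validate()
    G = np.asarray(getattr(gain, "values", gain), dtype=float)
    if G.shape[1] != mesh.n_vertices:
        raise ValueError(
            f"gain has {G.shape[1]} columns but mesh has {mesh.n_vertices} vertices"
        )
    if G.shape[0] != sensors.n_channels:
        raise ValueError("gain row count must equal sensor count")

    rng = _rng(cfg.seed, "simulate_recording")
    T = int(round(cfg.duration_s * cfg.fs))
    dwell_samples = cfg.state_dwell_ms * cfg.fs / 1000.0
    path = _markov_statepath(cfg.n_states, dwell_samples, T, rng)

    n_src_total = cfg.n_states * cfg.sources_per_state
    if n_src_total > mesh.n_vertices:
        raise ValueError("more sources requested than mesh vertices")
    src_vertices = rng.choice(mesh.n_vertices, size=n_src_total, replace=False)
    src_vertices = src_vertices.reshape(cfg.n_states, cfg.sources_per_state)

    courses = _bandlimited_courses(n_src_total, T, cfg.fs, rng)
    courses = courses.reshape(cfg.n_states, cfg.sources_per_state, T)

    data = np.zeros((sensors.n_channels, T))
    for k in range(cfg.n_states):
        active = path == k + 1
        if not active.any():
            continue
        gated = courses[k][:, active] * cfg.source_amplitude
        data[:, active] += G[:, src_vertices[k]] @ gated

    rec = SensorRecording(
        data=data,
        fs=cfg.fs,
        labels=list(sensors.labels),
        state_truth=path,
        meta={"seed": cfg.seed, "snr_db": cfg.snr_db,
              "source_vertices": src_vertices},
    )
    if cfg.snr_db is not None and cfg.source_amplitude != 0:
        rec = add_noise_db(rec, cfg.snr_db, seed=cfg.seed)
    return rec


def add_noise_db(rec: SensorRecording, snr_db: float, seed: int = 0) -> SensorRecording:
    """Add white Gaussian sensor noise at a target broadband SNR.

    SNR is defined on power pooled over all channels and samples:
    ``10*log10(mean signal power / mean noise power) = snr_db``.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    sig_power = float(np.mean(rec.data**2))
    if sig_power == 0.0:
        raise ValueError("SNR undefined for an all-zero recording")
    noise_power = sig_power / 10.0 ** (snr_db / 10.0)
    rng = _rng(seed, "add_noise_db")
    noise = rng.standard_normal(rec.data.shape) * np.sqrt(noise_power)
    meta = dict(rec.meta)
    meta["snr_db"] = snr_db
    return replace(rec, data=rec.data + noise, meta=meta)


def shuffle_channels(rec: SensorRecording, seed: int = 0) -> SensorRecording:
    """Permute data rows while channel labels keep their original order.

    Destroys the label <-> position <-> data correspondence (the benchmark's
    negative control) while preserving the multiset of channel time series.
    The applied permutation is stored in ``meta['permutation']`` so it can
    be inverted.
    """
    C = rec.n_channels
    if C < 2:
        warnings.warn("single-channel recording: shuffle is a no-op")
        return replace(rec, meta=dict(rec.meta, permutation=np.array([0])))
    rng = _rng(seed, "shuffle_channels")
    perm = rng.permutation(C)
    meta = dict(rec.meta)
    meta["permutation"] = perm
    return replace(rec, data=rec.data[perm], meta=meta)
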