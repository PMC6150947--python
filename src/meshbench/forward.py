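"""Lead fields for surface-normal current dipoles in a spherical conductor.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has the Sarvas closed form; conveniently it is independent of the
conductivity profile and the sphere radius, depending only on the centre.
A current dipole whose moment is radial (parallel to its position vector
from the sphere centre) produces exactly zero external field — the
"silent source" property — and this implementation returns exactly 0 in
that case, including for a dipole at the centre itself.

Units: positions in mm, dipole moments in nAm, fields in fT.
The gain interface accepts externally supplied matrices, so users with a
realistic (BEM/FEM) head model can inject their own lead fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .synthgen import CorticalMesh, SensorArray

__all__ = ["GainMatrix", "sarvas_leadfield", "gain_matrix"]

_MU0_OVER_4PI = 1e-7  # T*m/A
_MM = 1e-3  # mm -> m
_NAM = 1e-9  # nAm -> A*m
_FT = 1e15  # T -> fT


@dataclass
class GainMatrix:
    """Channels x sources lead-field matrix (fT per nAm)."""

    values: np.ndarray  # (C, N)
    channel_labels: list
    mesh_id: str = ""

    @property
    def shape(self):
        return self.values.shape

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("gain", data=self.values)
            f.create_dataset(
                "channel_labels",
                data=np.array(self.channel_labels, dtype=h5py.string_dtype()),
            )
            f.attrs["mesh_id"] = self.mesh_id

    @classmethod
    def load_h5(cls, path) -> "GainMatrix":
        with h5py.File(path, "r") as f:
            vals = f["gain"][()]
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in f["channel_labels"][()]
            ]
            mesh_id = str(f.attrs.get("mesh_id", ""))
        return cls(values=vals, channel_labels=labels, mesh_id=mesh_id)


def _sarvas_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Sarvas magnetic field B(r) (SI units) for dipoles r0, moments q.

    r0, q: (N, 3) dipole positions (m, relative to sphere centre) and
    moments (A*m); r: (3,) sensor position (m, relative to centre).
    Returns (N, 3) fields in tesla.
    """
    a_vec = r[None, :] - r0  # (N, 3)
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r)
    r0_dot_r = r0 @ r
    a_dot_r = a_vec @ r
    F = a * (rn * a + rn**2 - r0_dot_r)
    grad_F = (
        (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r[None, :]
        - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0
    )
    q_x_r0 = np.cross(q, r0)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = _MU0_OVER_4PI / F[:, None] ** 2 * (
            F[:, None] * q_x_r0 - (q_x_r0 @ r)[:, None] * grad_F
        )
    # Radial dipoles (q x r0 == 0) are exactly silent; this also covers a
    # dipole at the centre, where F-terms would otherwise be 0/0.
    silent = np.linalg.norm(q_x_r0, axis=1) == 0.0
    B[silent] = 0.0
    return B


def sarvas_leadfield(
    dipole_pos,
    dipole_moment,
    sensor_pos,
    sensor_ori,
    center=(0.0, 0.0, 0.0),
    conductor_radius: float | None = None,
) -> float:
    """Field (fT) at one magnetometer from one current dipole.

    ``dipole_pos``/``sensor_pos`` in mm, ``dipole_moment`` in nAm,
    ``sensor_ori`` the unit pickup direction. The sensor must lie strictly
    outside, and the dipole strictly inside, the conductor sphere (checked
    when ``conductor_radius`` is given).
    """
    center = np.asarray(center, float)
    r0 = (np.asarray(dipole_pos, float) - center) * _MM
    r = (np.asarray(sensor_pos, float) - center) * _MM
    if conductor_radius is not None:
        cr = conductor_radius * _MM
        if np.linalg.norm(r) <= cr:
            raise ValueError("sensor must be strictly outside the conductor sphere")
        if np.linalg.norm(r0) >= cr:
            raise ValueError("dipole must be strictly inside the conductor sphere")
    q = np.asarray(dipole_moment, float)[None, :] * _NAM
    B = _sarvas_field(r0[None, :], q, r)
    return float(B[0] @ np.asarray(sensor_ori, float)) * _FT


def gain_matrix(mesh: CorticalMesh, sensors: SensorArray, mesh_id: str = "") -> GainMatrix:
    """Lead fields for unit surface-normal dipoles at every mesh vertex.

    Column i is the field (all channels, fT) of a 1 nAm dipole at vertex i
    oriented along the vertex's outward normal.
    """
    center = np.asarray(sensors.conductor_center, float)
    r0 = (mesh.vertices - center) * _MM
    inside = np.linalg.norm(r0, axis=1) < sensors.conductor_radius * _MM
    if not inside.all():
        bad = np.flatnonzero(~inside)
        raise ValueError(
            f"{bad.size} vertices lie on/outside the conductor sphere: "
            f"indices {bad[:10].tolist()}..."
        )
    q = mesh.normals * _NAM  # 1 nAm along the normal
    G = np.empty((sensors.n_channels, mesh.n_vertices))
    for c in range(sensors.n_channels):
        r = (sensors.positions[c] - center) * _MM
        if np.linalg.norm(r) <= sensors.conductor_radius * _MM:
            raise ValueError(f"sensor {sensors.labels[c]} inside conductor")
        B = _sarvas_field(r0, q, r)
        G[c] = (B @ sensors.orientations[c]) * _FT
    return GainMatrix(values=G, channel_labels=list(sensors.labels), mesh_id=mesh_id)
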