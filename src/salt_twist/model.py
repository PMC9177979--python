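"""In-memory containers for duplex structures, trajectories and ion clouds.

Conventions used throughout the package:

* coordinates in Angstrom, time in ns, concentrations in mM, angles in degrees;
* chain ``A`` is strand I read 5'->3', chain ``B`` the complementary strand;
* residues are numbered 1-based per chain; base pair ``i`` (1-based) pairs
  chain A residue ``i`` with chain B residue ``n_bp + 1 - i``;
* residue names follow the PDB nucleic convention ``DA/DC/DG/DT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
BASE_OF_RESNAME = {v: k for k, v in RESNAME.items()}


def reverse_complement(sequence: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(sequence.upper()))
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"non-ACGT character in sequence: {exc}") from None


@dataclass
class ReferenceFrame:
    """Origin plus right-handed orthonormal triad (columns x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)

    def validate(self, tol: float = 1e-9) -> None:
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=tol):
            raise ValueError("frame axes are not orthonormal")
        if abs(np.linalg.det(self.axes) - 1.0) > tol:
            raise ValueError("frame axes are not right-handed (det != +1)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


class DuplexTopology:
    """Static atom table of a DNA duplex (identities, not coordinates)."""

    def __init__(
        self,
        sequence: str,
        chain_id: np.ndarray,
        res_id: np.ndarray,
        res_name: np.ndarray,
        atom_name: np.ndarray,
        element: np.ndarray,
    ) -> None:
        sequence = sequence.upper()
        if len(sequence) < 2:
            raise ValueError("duplex needs at least 2 bp")
        if any(b not in COMPLEMENT for b in sequence):
            bad = next(b for b in sequence if b not in COMPLEMENT)
            raise ValueError(f"non-ACGT character in sequence: {bad!r}")
        self.sequence = sequence
        self.chain_id = np.asarray(chain_id)
        self.res_id = np.asarray(res_id, dtype=int)
        self.res_name = np.asarray(res_name)
        self.atom_name = np.asarray(atom_name)
        self.element = np.asarray(element)
        self._index: dict[tuple[str, int, str], int] = {
            (c, int(r), a): i
            for i, (c, r, a) in enumerate(zip(self.chain_id, self.res_id, self.atom_name))
        }

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        try:
            return self._index[(chain, int(res_id), atom_name)]
        except KeyError:
            raise KeyError(
                f"atom {atom_name!r} of residue {chain}:{res_id} not present"
            ) from None

    def has_atom(self, chain: str, res_id: int, atom_name: str) -> bool:
        return (chain, int(res_id), atom_name) in self._index

    def base(self, chain: str, res_id: int) -> str:
        """One-letter base of a residue."""
        if chain == "A":
            return self.sequence[res_id - 1]
        return COMPLEMENT[self.sequence[self.n_bp - res_id]]

    def paired_residues(self, bp: int) -> tuple[int, int]:
        """(chain A res_id, chain B res_id) of 1-based base pair ``bp``."""
        if not 1 <= bp <= self.n_bp:
            raise IndexError(f"base pair index {bp} out of range")
        return bp, self.n_bp + 1 - bp

    def select(self, atom_names, chain: str | None = None) -> np.ndarray:
        """Boolean mask over atoms by name (and optionally chain)."""
        names = {atom_names} if isinstance(atom_names, str) else set(atom_names)
        mask = np.isin(self.atom_name, list(names))
        if chain is not None:
            mask &= self.chain_id == chain
        return mask


@dataclass
class DuplexConformation:
    """One frame of a duplex: topology plus coordinates (n_atoms, 3) in A."""

    topology: DuplexTopology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError("coordinate array does not match topology")

    @property
    def n_bp(self) -> int:
        return self.topology.n_bp

    def atom(self, chain: str, res_id: int, atom_name: str) -> np.ndarray:
        return self.coords[self.topology.atom_index(chain, res_id, atom_name)]

    def transformed(self, R: np.ndarray, t: np.ndarray = (0.0, 0.0, 0.0)) -> "DuplexConformation":
        """Rigidly moved copy (rotation matrix R, translation t)."""
        return DuplexConformation(self.topology, self.coords @ np.asarray(R).T + np.asarray(t, float))


@dataclass
class Trajectory:
    """Ordered duplex frames sharing one topology."""

    topology: DuplexTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError("trajectory coordinates must be (n_frames, n_atoms, 3)")
        if self.times_ns is None:
            self.times_ns = np.arange(self.n_frames, dtype=float)
        else:
            self.times_ns = np.asarray(self.times_ns, dtype=float)
            if self.times_ns.shape != (self.n_frames,):
                raise ValueError("times_ns must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bp(self) -> int:
        return self.topology.n_bp

    def frame(self, i: int) -> DuplexConformation:
        return DuplexConformation(self.topology, self.coords[i])

    def transformed(self, R: np.ndarray, t: np.ndarray = (0.0, 0.0, 0.0)) -> "Trajectory":
        return Trajectory(self.topology, self.coords @ np.asarray(R).T + np.asarray(t, float), self.times_ns)

    @staticmethod
    def from_conformations(confs) -> "Trajectory":
        confs = list(confs)
        return Trajectory(confs[0].topology, np.stack([c.coords for c in confs]))


@dataclass
class IonFrames:
    """Ion positions per frame, with species labels and valences per ion."""

    species: np.ndarray  # (n_ions,) str labels, e.g. "K", "MG"
    valence: np.ndarray  # (n_ions,) int
    coords: np.ndarray  # (n_frames, n_ions, 3)
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species)
        self.valence = np.asarray(self.valence, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("ion positions must be finite")
        if self.coords.shape[1] != len(self.species):
            raise ValueError("species labels must match ion count")
        if self.times_ns is None:
            self.times_ns = np.arange(self.n_frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_ions(self) -> int:
        return self.coords.shape[1]

    @property
    def species_set(self) -> list[str]:
        return sorted(set(self.species.tolist()))


@dataclass
class TwistSeries:
    """Per-frame twist per bp for one twist definition."""

    method: str
    twist_deg_bp: np.ndarray
    times_ns: np.ndarray | None = None
    reference_deg_bp: float | None = None

    VALID_METHODS = ("local_helical", "bp_twist", "end_to_end")

    def __post_init__(self) -> None:
        if self.method not in self.VALID_METHODS:
            raise ValueError(f"unknown twist method {self.method!r}")
        self.twist_deg_bp = np.atleast_1d(np.asarray(self.twist_deg_bp, dtype=float))
        if self.times_ns is None:
            self.times_ns = np.arange(len(self.twist_deg_bp), dtype=float)

    @property
    def delta(self) -> np.ndarray:
        """Twist change relative to the stated reference (or series mean)."""
        ref = self.reference_deg_bp
        if ref is None:
            ref = float(self.twist_deg_bp.mean())
        return self.twist_deg_bp - ref


@dataclass
class RotExtCurve:
    """Magnetic-tweezers rotation-extension curve."""

    turns: np.ndarray
    ext_um: np.ndarray
    ext_sd: np.ndarray | None = None
    force_pn: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.turns = np.asarray(self.turns, dtype=float)
        self.ext_um = np.asarray(self.ext_um, dtype=float)
        if len(self.turns) < 5:
            raise ValueError("rotation-extension curve needs >= 5 points")
        if np.any(np.diff(self.turns) <= 0):
            raise ValueError("turns must be strictly increasing")
        if self.ext_sd is not None:
            self.ext_sd = np.asarray(self.ext_sd, dtype=float)


@dataclass
class ConcSeries:
    """Twist change vs ion concentration with per-point uncertainties."""

    conc_mM: np.ndarray
    dtw_deg_bp: np.ndarray
    sigma: np.ndarray
    ion: str = ""
    valence: int = 1

    def __post_init__(self) -> None:
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        self.dtw_deg_bp = np.asarray(self.dtw_deg_bp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.conc_mM <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be positive")
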