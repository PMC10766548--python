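"""Domain types, unit conventions, and extended-XYZ readers/writers.

Internal units are fixed package-wide: energies in kcal/mol, lengths in Å,
time in fs, masses in amu.  Every other module consumes the types defined
here and never re-parses files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "UNITS",
    "ATOMIC_MASSES",
    "Configuration",
    "LabeledSample",
    "Dataset",
    "UnitSystem",
    "ExtXYZParseError",
    "read_extxyz",
    "write_extxyz",
    "save_dataset",
    "load_dataset",
]

# kcal/mol, Å, fs, amu throughout.
#   1 kcal/mol / amu = 4.184e-4 Å²/fs²  (4184 J/mol, 1 amu = 1e-3 kg/mol)
FORCE_TO_ACCEL = 4.184e-4  # (kcal/mol/Å)/amu -> Å/fs²
KINETIC_TO_ENERGY = 1.0 / FORCE_TO_ACCEL  # amu·Å²/fs² -> kcal/mol


@dataclass(frozen=True)
class UnitSystem:
    """The single package-wide unit convention."""

    energy: str = "kcal/mol"
    length: str = "Angstrom"
    time: str = "fs"
    mass: str = "amu"
    boltzmann_constant: float = 0.0019872041  # kcal/(mol·K)


UNITS = UnitSystem()

# Standard atomic weights for the elements the toy systems use; "X" is a
# generic unit-mass point particle for 2D landscape toys.
ATOMIC_MASSES: dict[str, float] = {
    "X": 1.0,
    "H": 1.008,
    "He": 4.0026,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
}


@dataclass
class Configuration:
    """An atomic configuration: the unit of all sampling.

    Parameters
    ----------
    species : list of element symbols, length N_A.
    positions : (N_A, 3) Cartesian coordinates, Å.
    velocities : optional (N_A, 3) velocities, Å/fs.
    tag : free-text provenance label.
    """

    species: list[str]
    positions: np.ndarray
    velocities: np.ndarray | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.positions):
            raise ValueError(
                f"species length {len(self.species)} != positions length "
                f"{len(self.positions)}"
            )
        if self.n_atoms < 1:
            raise ValueError("a configuration needs at least one atom")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions shape")
        m = self.masses
        if np.any(m <= 0):
            raise ValueError("masses must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[s] for s in self.species], dtype=float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"no mass tabulated for element {exc}") from exc

    def copy(self) -> "Configuration":
        return Configuration(
            species=list(self.species),
            positions=self.positions.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            tag=self.tag,
        )

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol (zero if velocities are unset)."""
        if self.velocities is None:
            return 0.0
        v2 = np.sum(self.velocities**2, axis=1)
        return 0.5 * float(np.dot(self.masses, v2)) * KINETIC_TO_ENERGY

    def temperature(self) -> float:
        """Instantaneous kinetic temperature, K, 3N degrees of freedom."""
        ndof = 3 * self.n_atoms
        return 2.0 * self.kinetic_energy() / (ndof * UNITS.boltzmann_constant)


@dataclass
class LabeledSample:
    """A configuration with its oracle energy (kcal/mol) and forces (kcal/mol/Å)."""

    configuration: Configuration
    energy: float
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.energy = float(self.energy)
        self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
        if self.forces.shape != self.configuration.positions.shape:
            raise ValueError("forces shape must match positions shape")


@dataclass
class Dataset:
    """Ordered collection of labeled samples with per-sample provenance.

    ``provenance[i]`` is the active-learning iteration that produced sample
    ``i`` (0 for the initial seed set).  Iteration indices must be
    non-decreasing in append order: datasets only ever grow.
    """

    samples: list[LabeledSample] = field(default_factory=list)
    provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.provenance):
            raise ValueError("provenance length must match samples length")
        self._check_monotone()

    def _check_monotone(self) -> None:
        if any(b < a for a, b in zip(self.provenance, self.provenance[1:])):
            raise ValueError("provenance iteration indices must be non-decreasing")

    def __len__(self) -> int:
        return len(self.samples)

    def append(self, sample: LabeledSample, iteration: int) -> None:
        if self.provenance and iteration < self.provenance[-1]:
            raise ValueError("cannot append a sample from an earlier iteration")
        self.samples.append(sample)
        self.provenance.append(int(iteration))

    def extend(self, samples: list[LabeledSample], iteration: int) -> None:
        for s in samples:
            self.append(s, iteration)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.samples], dtype=float)

    def configurations(self) -> list[Configuration]:
        return [s.configuration for s in self.samples]

    def subset(self, indices) -> "Dataset":
        return Dataset(
            samples=[self.samples[i] for i in indices],
            provenance=[self.provenance[i] for i in indices],
        )


class ExtXYZParseError(ValueError):
    """Malformed extended-XYZ input; the message names the offending line."""


def _parse_comment(line: str) -> dict[str, str]:
    """Parse ``key=value`` pairs from an extended-XYZ comment line."""
    out: dict[str, str] = {}
    i, n = 0, len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        if i >= n:
            break
        j = i
        while j < n and line[j] not in "= \t":
            j += 1
        key = line[i:j]
        if j < n and line[j] == "=":
            j += 1
            if j < n and line[j] == '"':
                k = line.find('"', j + 1)
                if k == -1:
                    raise ExtXYZParseError(f"unterminated quote in comment: {line!r}")
                out[key] = line[j + 1 : k]
                j = k + 1
            else:
                k = j
                while k < n and not line[k].isspace():
                    k += 1
                out[key] = line[j:k]
                j = k
        else:
            out[key] = ""
        i = j
    return out


def _parse_properties(spec: str, lineno: int) -> list[tuple[str, str, int]]:
    fields = spec.split(":")
    if len(fields) % 3 != 0:
        raise ExtXYZParseError(f"line {lineno}: malformed Properties spec {spec!r}")
    out = []
    for i in range(0, len(fields), 3):
        name, kind, ncol = fields[i], fields[i + 1], fields[i + 2]
        try:
            out.append((name, kind, int(ncol)))
        except ValueError:
            raise ExtXYZParseError(
                f"line {lineno}: non-integer column count in Properties {spec!r}"
            ) from None
    return out


def read_extxyz(path) -> list[Configuration | LabeledSample]:
    """Read an extended-XYZ file into configurations.

    Frames whose comment line carries an ``energy=`` key (and, optionally,
    per-atom ``forces`` columns) come back as :class:`LabeledSample`;
    unlabeled frames come back as plain :class:`Configuration`.  Coordinates
    are taken as Å, energies as kcal/mol.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Configuration | LabeledSample] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ExtXYZParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms < 1:
            raise ExtXYZParseError(f"line {i + 1}: atom count must be >= 1")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 >= len(lines):
            raise ExtXYZParseError(f"line {i + 1}: truncated frame header")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        keys = _parse_comment(comment)
        props = _parse_properties(
            keys.get("Properties", "species:S:1:pos:R:3"), i + 2
        )
        if i + 2 + natoms > len(lines):
            raise ExtXYZParseError(
                f"line {i + 1}: frame declares {natoms} atoms but file ends early"
            )
        species: list[str] = []
        positions = np.zeros((natoms, 3))
        forces: np.ndarray | None = None
        has_forces = any(name == "forces" for name, _, _ in props)
        if has_forces:
            forces = np.zeros((natoms, 3))
        ncols = sum(nc for _, _, nc in props)
        for a in range(natoms):
            lineno = i + 3 + a
            toks = lines[i + 2 + a].split()
            if len(toks) != ncols:
                raise ExtXYZParseError(
                    f"line {lineno}: expected {ncols} columns, got {len(toks)}"
                )
            col = 0
            for name, kind, nc in props:
                vals = toks[col : col + nc]
                col += nc
                try:
                    if name == "species":
                        species.append(vals[0])
                    elif name == "pos":
                        positions[a] = [float(v) for v in vals]
                    elif name == "forces":
                        forces[a] = [float(v) for v in vals]
                except ValueError:
                    raise ExtXYZParseError(
                        f"line {lineno}: non-numeric value in field {name!r}"
                    ) from None
        config = Configuration(
            species=species, positions=positions, tag=keys.get("tag", "")
        )
        if "energy" in keys:
            try:
                energy = float(keys["energy"])
            except ValueError:
                raise ExtXYZParseError(
                    f"line {i + 2}: non-numeric energy= value {keys['energy']!r}"
                ) from None
            frames.append(
                LabeledSample(
                    configuration=config,
                    energy=energy,
                    forces=forces if forces is not None else np.zeros((natoms, 3)),
                )
            )
        else:
            frames.append(config)
        i += 2 + natoms
    return frames


def write_extxyz(frames, path, extra_keys: list[dict] | None = None) -> None:
    """Write configurations or labeled samples as extended-XYZ.

    Uses the de-facto-standard dialect: ``Properties=species:S:1:pos:R:3``
    (plus ``:forces:R:3`` for labeled frames) with ``energy=`` on the comment
    line.  Formatting is deterministic (fixed 12-decimal fields).

    ``extra_keys`` optionally supplies one dict of additional comment-line
    key/value pairs per frame (used for per-frame ``rho=`` in trajectories).
    """
    if not frames:
        raise ValueError("refusing to write an empty frame list")
    out_lines: list[str] = []
    for fi, frame in enumerate(frames):
        if isinstance(frame, LabeledSample):
            config, energy, forces = frame.configuration, frame.energy, frame.forces
        else:
            config, energy, forces = frame, None, None
        keys = []
        if energy is not None:
            keys.append(f"energy={energy:.12f}")
        if extra_keys is not None:
            for k, v in extra_keys[fi].items():
                keys.append(f"{k}={v:.12f}" if isinstance(v, float) else f"{k}={v}")
        props = "species:S:1:pos:R:3" + (":forces:R:3" if forces is not None else "")
        keys.append(f"Properties={props}")
        if config.tag:
            keys.append(f'tag="{config.tag}"')
        out_lines.append(str(config.n_atoms))
        out_lines.append(" ".join(keys))
        for a in range(config.n_atoms):
            cols = [f"{config.species[a]:2s}"]
            cols += [f"{x:20.12f}" for x in config.positions[a]]
            if forces is not None:
                cols += [f"{x:20.12f}" for x in forces[a]]
            out_lines.append(" ".join(cols))
    Path(path).write_text("\n".join(out_lines) + "\n")


def save_dataset(dataset: Dataset, directory) -> None:
    """Persist a dataset as extended-XYZ samples plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_extxyz(dataset.samples, directory / "samples.xyz")
    manifest = {
        "n_samples": len(dataset),
        "provenance": dataset.provenance,
        "tags": [s.configuration.tag for s in dataset.samples],
        "units": {"energy": UNITS.energy, "length": UNITS.length},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    frames = read_extxyz(directory / "samples.xyz")
    samples: list[LabeledSample] = []
    for frame, tag in zip(frames, manifest["tags"]):
        if not isinstance(frame, LabeledSample):
            raise ValueError("dataset frames must carry energy labels")
        frame.configuration.tag = tag
        samples.append(frame)
    return Dataset(samples=samples, provenance=list(manifest["provenance"]))
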