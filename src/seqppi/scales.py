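"""Amino-acid physicochemical scales and their normalization.

A scale maps each of the 20 standard residues to a real number. Before use,
every scale is standardized to mean 0 and population standard deviation 1
(divisor 20) over the 20 residues. The default configuration bundles seven
scales, in this fixed order:

1. hydrophobicity
2. hydrophilicity
3. side_chain_volume
4. polarity
5. polarizability
6. solvent_accessible_surface_area
7. net_charge_index

The numeric tables ship as plain-text package data (``seqppi/data/*.txt``,
two whitespace-separated columns, ``#`` comments carry provenance) so users
can audit or substitute them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

STANDARD_AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Default scale order; index 0..6 corresponds to scale index j = 1..7.
DEFAULT_SCALE_NAMES: tuple[str, ...] = (
    "hydrophobicity",
    "hydrophilicity",
    "side_chain_volume",
    "polarity",
    "polarizability",
    "solvent_accessible_surface_area",
    "net_charge_index",
)

_MEAN_TOL = 1e-9


class ScaleError(ValueError):
    """Raised for malformed or degenerate amino-acid scales."""


@dataclass(frozen=True)
class AminoAcidScale:
    """A raw per-residue descriptor over the 20 standard amino acids."""

    name: str
    raw_values: Mapping[str, float]
    source_ref: str = ""

    def __post_init__(self) -> None:
        _check_coverage(self.name, self.raw_values)


@dataclass(frozen=True)
class NormalizedScale:
    """A scale standardized to mean 0 / population s.d. 1 over 20 residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_coverage(self.name, self.values)

    def __getitem__(self, code: str) -> float:
        return self.values[code]


def _check_coverage(name: str, values: Mapping[str, float]) -> None:
    missing = [aa for aa in STANDARD_AMINO_ACIDS if aa not in values]
    if missing:
        raise ScaleError(
            f"scale {name!r} is missing amino acid(s): {', '.join(missing)}"
        )
    extra = sorted(set(values) - set(STANDARD_AMINO_ACIDS))
    if extra:
        raise ScaleError(
            f"scale {name!r} has non-standard code(s): {', '.join(extra)}"
        )
    bad = [aa for aa in STANDARD_AMINO_ACIDS if not math.isfinite(values[aa])]
    if bad:
        raise ScaleError(f"scale {name!r} has non-finite value(s) at: {', '.join(bad)}")


def normalize_scale(raw: AminoAcidScale) -> NormalizedScale:
    """Standardize a raw scale: ``P'_i = (P_i - mean) / sd`` with the mean and
    *population* standard deviation (divisor 20) taken over the 20 residues.

    Raises
    ------
    ScaleError
        If the scale has zero variance ("degenerate scale") or does not
        cover the 20 standard residues.
    """
    vals = [float(raw.raw_values[aa]) for aa in STANDARD_AMINO_ACIDS]
    mean = sum(vals) / 20.0
    var = sum((v - mean) ** 2 for v in vals) / 20.0
    if var == 0.0:
        raise ScaleError(f"degenerate scale: {raw.name!r} has zero variance")
    sd = math.sqrt(var)
    return NormalizedScale(
        name=raw.name,
        values={aa: (float(raw.raw_values[aa]) - mean) / sd for aa in STANDARD_AMINO_ACIDS},
    )


@dataclass(frozen=True)
class ScaleSet:
    """An ordered collection of normalized scales (default length 7)."""

    scales: tuple[NormalizedScale, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self) -> Iterator[NormalizedScale]:
        return iter(self.scales)

    def __getitem__(self, i: int) -> NormalizedScale:
        return self.scales[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scales)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown scale {name!r}; available: {', '.join(self.names)}"
            ) from None

    def subset(self, names: Sequence[str]) -> "ScaleSet":
        return ScaleSet(tuple(self.scales[self.index_of(n)] for n in names))


def read_scale_file(text: str, name: str) -> AminoAcidScale:
    """Parse a two-column scale table (code, value; ``#`` comments allowed)."""
    values: dict[str, float] = {}
    source_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            source_lines.append(line.lstrip("# "))
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ScaleError(f"scale table {name!r}, line {lineno}: expected 2 columns")
        code, raw = parts
        try:
            values[code.upper()] = float(raw)
        except ValueError:
            raise ScaleError(
                f"scale table {name!r}, line {lineno}: bad value {raw!r}"
            ) from None
    return AminoAcidScale(name=name, raw_values=values, source_ref=" ".join(source_lines))


def load_raw_scale(name: str) -> AminoAcidScale:
    """Load one bundled raw scale table by name."""
    fname = f"{name}.txt"
    try:
        text = resources.files("seqppi.data").joinpath(fname).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ScaleError(f"bundled scale table missing or unreadable: {fname}") from exc
    return read_scale_file(text, name)


def load_default_scale_set(names: Sequence[str] | None = None) -> ScaleSet:
    """Load the bundled scales, normalized, in the documented order.

    Parameters
    ----------
    names:
        Optional subset/reordering by scale name. Defaults to the full
        seven-scale set.
    """
    if names is None:
        names = DEFAULT_SCALE_NAMES
    unknown = [n for n in names if n not in DEFAULT_SCALE_NAMES]
    if unknown:
        raise ScaleError(
            f"unknown scale name(s): {', '.join(unknown)}; "
            f"bundled scales: {', '.join(DEFAULT_SCALE_NAMES)}"
        )
    return ScaleSet(tuple(normalize_scale(load_raw_scale(n)) for n in names))
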