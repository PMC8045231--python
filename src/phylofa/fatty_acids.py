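"""Fatty-acid nomenclature and composition-level indices.

Fatty acids are identified by the shorthand ``C<carbons>:<double bonds>`` with
an optional omega-class suffix, e.g. ``C16:0`` (palmitic acid), ``C18:1n9``
(oleic acid), ``C22:6n3`` (docosahexaenoic acid).  A composition is a
species-by-fatty-acid table of molar percentages closing to 100 per species.

The indices computed here summarise a composition along the axes relevant to
membrane physiology:

* class sums — saturated (SFA), monounsaturated (MUFA) and polyunsaturated
  (PUFA) mol%, and the fraction of n-3 PUFA within total PUFA;
* ACL — average chain length, the proportion-weighted mean number of carbons;
* DBI — double bond index, mean number of double bonds per 100 fatty acids;
* PI — peroxidizability index, a weighted unsaturation sum with coefficients
  0.025, 1, 2, 4, 6, 8 for mono- through hexaenoic acids, reflecting the
  empirical susceptibility of each unsaturation class to lipid peroxidation;
* AI — anti-inflammatory index, the percentage ratio of the anti-inflammatory
  acids 20:3n-6, 20:5n-3 and 22:6n-3 to pro-inflammatory arachidonic acid
  20:4n-6.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcidDescriptor",
    "CompositionTable",
    "parse_fa_label",
    "class_sums",
    "acl",
    "dbi",
    "peroxidizability_index",
    "anti_inflammatory_index",
    "compute_indices",
    "PI_COEFFICIENTS",
    "AI_NUMERATOR",
    "AI_DENOMINATOR",
]

#: Peroxidizability coefficients keyed on the number of double bonds.
#: Saturated acids contribute nothing; no coefficient is defined beyond
#: hexaenoic (6 double bonds).
PI_COEFFICIENTS: dict[int, float] = {0: 0.0, 1: 0.025, 2: 1.0, 3: 2.0, 4: 4.0, 5: 6.0, 6: 8.0}

#: The anti-inflammatory index is an explicit enumeration: these three acids
#: over arachidonic acid.  Acids outside the enumeration contribute nothing.
AI_NUMERATOR: tuple[str, ...] = ("C20:3n6", "C20:5n3", "C22:6n3")
AI_DENOMINATOR: str = "C20:4n6"

_LABEL_RE = re.compile(r"^C(?P<carbons>\d+):(?P<bonds>\d+)(?:n(?P<omega>\d+))?$")


class FattyAcidParseError(ValueError):
    """Raised when a fatty-acid label does not follow the C<x>:<y>[n<z>] form."""


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """A parsed fatty-acid name.

    Attributes
    ----------
    label : canonical label, e.g. ``"C20:4n6"``.
    chain_length : number of carbons (>= 4).
    n_double_bonds : number of double bonds (>= 0).
    omega_class : ``"n3"``, ``"n6"``, ``"n7"``, ``"n9"`` or ``"none"`` for
        saturated acids.
    sat_class : ``"SFA"`` (0 bonds), ``"MUFA"`` (1) or ``"PUFA"`` (>= 2).
    """

    label: str
    chain_length: int
    n_double_bonds: int
    omega_class: str
    sat_class: str

    def __post_init__(self) -> None:
        if self.chain_length < 4:
            raise FattyAcidParseError(
                f"{self.label!r}: chain length {self.chain_length} < 4"
            )
        expected = "SFA" if self.n_double_bonds == 0 else (
            "MUFA" if self.n_double_bonds == 1 else "PUFA"
        )
        if self.sat_class != expected:
            raise FattyAcidParseError(
                f"{self.label!r}: saturation class {self.sat_class} inconsistent "
                f"with {self.n_double_bonds} double bonds"
            )
        if self.omega_class == "none" and self.n_double_bonds != 0:
            raise FattyAcidParseError(
                f"{self.label!r}: unsaturated acid must carry an omega class"
            )


def parse_fa_label(label: str) -> FattyAcidDescriptor:
    """Parse a shorthand fatty-acid label such as ``"C18:2n6"``.

    Raises :class:`FattyAcidParseError` naming the offending token on
    malformed input.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise FattyAcidParseError(f"malformed fatty-acid label: {label!r}")
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds"))
    omega = m.group("omega")
    omega_class = "none" if omega is None else f"n{int(omega)}"
    if bonds == 0 and omega is not None:
        raise FattyAcidParseError(
            f"{label!r}: saturated acid cannot carry omega class n{omega}"
        )
    if bonds > 0 and omega is None:
        raise FattyAcidParseError(
            f"{label!r}: unsaturated acid requires an omega class (e.g. n3)"
        )
    sat_class = "SFA" if bonds == 0 else ("MUFA" if bonds == 1 else "PUFA")
    return FattyAcidDescriptor(
        label=f"C{carbons}:{bonds}" + ("" if omega is None else f"n{int(omega)}"),
        chain_length=carbons,
        n_double_bonds=bonds,
        omega_class=omega_class,
        sat_class=sat_class,
    )


@dataclass
class CompositionTable:
    """Species-by-fatty-acid molar percentages with a closure invariant.

    Rows are species, columns fatty acids; each row must sum to 100 within
    ``closure_tol`` (default 0.5 mol%, since published species means need not
    close exactly).  ``renormalize()`` rescales rows to close exactly; it is
    never applied implicitly.
    """

    species: list[str]
    fatty_acids: list[FattyAcidDescriptor]
    proportions: np.ndarray
    closure_tol: float = 0.5

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.species), len(self.fatty_acids)):
            raise ValueError(
                f"proportions shape {self.proportions.shape} does not match "
                f"{len(self.species)} species x {len(self.fatty_acids)} fatty acids"
            )
        if len(set(self.species)) != len(self.species):
            dupes = sorted({s for s in self.species if self.species.count(s) > 1})
            raise ValueError(f"duplicate species identifiers: {dupes}")
        labels = [fa.label for fa in self.fatty_acids]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate fatty-acid columns")
        if np.any(self.proportions < 0):
            raise ValueError("negative molar proportions")
        rowsums = self.proportions.sum(axis=1)
        bad = np.abs(rowsums - 100.0) > self.closure_tol
        if np.any(bad):
            offenders = [self.species[i] for i in np.flatnonzero(bad)[:5]]
            raise ValueError(
                f"rows do not close to 100 mol% within ±{self.closure_tol}: "
                f"{offenders} (sums {rowsums[bad][:5].round(3).tolist()})"
            )

    @property
    def labels(self) -> list[str]:
        return [fa.label for fa in self.fatty_acids]

    def renormalize(self) -> "CompositionTable":
        """Return a copy with rows rescaled to sum to exactly 100."""
        scaled = 100.0 * self.proportions / self.proportions.sum(axis=1, keepdims=True)
        return CompositionTable(list(self.species), list(self.fatty_acids), scaled,
                                closure_tol=self.closure_tol)

    def column(self, label: str) -> np.ndarray:
        """mol% column for one fatty acid (zeros if the acid is absent)."""
        try:
            j = self.labels.index(label)
        except ValueError:
            return np.zeros(len(self.species))
        return self.proportions[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=pd.Index(self.species, name="species"),
                            columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, closure_tol: float = 0.5) -> "CompositionTable":
        fas = [parse_fa_label(c) for c in df.columns]
        return cls(list(df.index.astype(str)), fas, df.to_numpy(dtype=float),
                   closure_tol=closure_tol)

    @classmethod
    def read_csv(cls, path: str | Path, sep: str = ",", closure_tol: float = 0.5) -> "CompositionTable":
        """Read a composition table: first column species id, remaining columns
        fatty-acid labels in the C<x>:<y>n<z> dialect."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_dataframe(df, closure_tol=closure_tol)

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep)


def _series(values: np.ndarray, comp: CompositionTable, name: str) -> pd.Series:
    return pd.Series(values, index=pd.Index(comp.species, name="species"), name=name)


def class_sums(comp: CompositionTable) -> pd.DataFrame:
    """Per-species SFA, MUFA, PUFA mol% sums and the n-3 PUFA / total PUFA fraction.

    The ratio is stored as a fraction in [0, 1] (the scale the beta-regression
    model requires).  Species with zero total PUFA get a missing ratio and a
    warning.
    """
    sat = np.array([fa.sat_class for fa in comp.fatty_acids])
    omega = np.array([fa.omega_class for fa in comp.fatty_acids])
    out = {}
    for cls_name in ("SFA", "MUFA", "PUFA"):
        out[cls_name] = comp.proportions[:, sat == cls_name].sum(axis=1)
    n3pufa = comp.proportions[:, (sat == "PUFA") & (omega == "n3")].sum(axis=1)
    total_pufa = out["PUFA"]
    ratio = np.full(len(comp.species), np.nan)
    nz = total_pufa > 0
    ratio[nz] = n3pufa[nz] / total_pufa[nz]
    if np.any(~nz):
        warnings.warn(
            f"{int((~nz).sum())} species have zero total PUFA; "
            "n3/total PUFA reported as missing",
            stacklevel=2,
        )
    out["n3_over_total_pufa"] = ratio
    return pd.DataFrame(out, index=pd.Index(comp.species, name="species"))


def acl(comp: CompositionTable) -> pd.Series:
    """Average chain length: mol-fraction-weighted mean number of carbons."""
    chains = np.array([fa.chain_length for fa in comp.fatty_acids], dtype=float)
    return _series(comp.proportions @ chains / 100.0, comp, "ACL")


def dbi(comp: CompositionTable) -> pd.Series:
    """Double bond index: mean number of double bonds per 100 fatty acids."""
    bonds = np.array([fa.n_double_bonds for fa in comp.fatty_acids], dtype=float)
    return _series(comp.proportions @ bonds, comp, "DBI")


def peroxidizability_index(comp: CompositionTable) -> pd.Series:
    """Peroxidizability index with coefficients 0.025/1/2/4/6/8 for 1-6 bonds.

    Acids with more than six double bonds have no defined coefficient and
    raise a ``ValueError`` (no extrapolation).
    """
    over = [fa.label for fa in comp.fatty_acids if fa.n_double_bonds > 6]
    if over:
        raise ValueError(
            f"no peroxidizability coefficient defined beyond hexaenoic: {over}"
        )
    coefs = np.array([PI_COEFFICIENTS[fa.n_double_bonds] for fa in comp.fatty_acids])
    return _series(comp.proportions @ coefs, comp, "PI")


def anti_inflammatory_index(comp: CompositionTable) -> pd.Series:
    """Anti-inflammatory index: 100 x (20:3n-6 + 20:5n-3 + 22:6n-3) / 20:4n-6.

    Requires arachidonic acid (C20:4n6) as a column; species where it is 0
    mol% get a missing value with a warning.
    """
    if AI_DENOMINATOR not in comp.labels:
        raise ValueError(
            f"anti-inflammatory index requires {AI_DENOMINATOR} in the table"
        )
    denom = comp.column(AI_DENOMINATOR)
    numer = sum(comp.column(lbl) for lbl in AI_NUMERATOR)
    ai = np.full(len(comp.species), np.nan)
    nz = denom > 0
    ai[nz] = 100.0 * numer[nz] / denom[nz]
    if np.any(~nz):
        warnings.warn(
            f"{int((~nz).sum())} species have zero arachidonic acid; "
            "AI reported as missing",
            stacklevel=2,
        )
    return _series(ai, comp, "AI")


def compute_indices(comp: CompositionTable) -> pd.DataFrame:
    """All composition-level indices as one per-species table.

    Columns: SFA, MUFA, PUFA, n3_over_total_pufa, ACL, DBI, PI, AI.
    """
    out = class_sums(comp)
    out["ACL"] = acl(comp)
    out["DBI"] = dbi(comp)
    out["PI"] = peroxidizability_index(comp)
    out["AI"] = anti_inflammatory_index(comp)
    return out


def write_indices_csv(comp: CompositionTable, path: str | Path,
                      renormalize: bool = False) -> pd.DataFrame:
    """Compute all indices and write them as CSV; returns the table."""
    table = compute_indices(comp.renormalize() if renormalize else comp)
    table.to_csv(path)
    return table
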