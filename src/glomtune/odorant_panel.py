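"""Odorant panel handling and vapor-phase concentration estimation.

An odorant panel is the ordered list of stimuli used in a glomerular imaging
experiment: each odorant carries a short id code, a human-readable name, a
nominal structural-class label (functional group / scaffold grouping, or
``MIXED`` for odorants with mixed group-defining features), an optional
SMILES string, and the metadata needed to estimate the vapor-phase
concentration delivered by the olfactometer.

Delivered concentrations are estimated under Raoult's law: the odorant and
its solvent are treated as an ideal mixture, so the odorant's partial
pressure in the reservoir headspace is its liquid mole fraction times its
pure-compound vapor pressure.  The headspace molarity is then scaled by the
olfactometer's air-dilution factor.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
logger = logging.getLogger(__name__)

#: molar gas constant, J/(mol K)
R_GAS = 8.31446261815324

#: defaults: 25 degC, 1 atm
T_DEFAULT = 298.15
P_ATM_DEFAULT = 101325.0

MIXED = "MIXED"


class PanelValidationError(ValueError):
    """Raised when a panel file violates its invariants (e.g. duplicate ids)."""


@dataclass
class Odorant:
    """One odorant of the panel.

    ``vapor_pressure`` is the pure-compound vapor pressure in Pa at 25 degC;
    ``liquid_mole_fraction`` is the dilution of the odorant in its liquid
    solvent reservoir; ``est_concentration`` is the estimated delivered
    vapor-phase concentration in mol/L (absent if not estimable).
    """

    id: str
    name: str
    structural_class: str
    smiles: str | None = None
    vapor_pressure: float | None = None
    liquid_mole_fraction: float | None = None
    est_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.liquid_mole_fraction is not None and not (
            0.0 <= self.liquid_mole_fraction <= 1.0
        ):
            raise PanelValidationError(
                f"odorant {self.id!r}: liquid_mole_fraction "
                f"{self.liquid_mole_fraction} outside [0, 1]"
            )
        if self.vapor_pressure is not None and self.vapor_pressure < 0:
            raise PanelValidationError(
                f"odorant {self.id!r}: negative vapor pressure"
            )
        if self.est_concentration is not None and self.est_concentration < 0:
            raise PanelValidationError(
                f"odorant {self.id!r}: negative estimated concentration"
            )


@dataclass
class OdorantPanel:
    """Ordered odorant list; file order defines display and class order."""

    odorants: list[Odorant]
    class_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [o.id for o in self.odorants]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise PanelValidationError(f"duplicate odorant ids: {dupes}")
        if not self.class_order:
            seen: dict[str, None] = {}
            for o in self.odorants:
                if o.structural_class != MIXED:
                    seen.setdefault(o.structural_class, None)
            self.class_order = list(seen)
        for o in self.odorants:
            if o.structural_class != MIXED and o.structural_class not in self.class_order:
                raise PanelValidationError(
                    f"odorant {o.id!r}: class {o.structural_class!r} not in class order"
                )

    def __len__(self) -> int:
        return len(self.odorants)

    def __iter__(self):
        return iter(self.odorants)

    @property
    def ids(self) -> list[str]:
        return [o.id for o in self.odorants]

    @property
    def classes(self) -> dict[str, str]:
        """Mapping odorant id -> structural class label."""
        return {o.id: o.structural_class for o in self.odorants}

    def get(self, odorant_id: str) -> Odorant:
        for o in self.odorants:
            if o.id == odorant_id:
                return o
        raise KeyError(odorant_id)


def _validate_smiles(smiles: str, odorant_id: str) -> str | None:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        mol = Chem.MolFromSmiles(smiles)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if mol is None:
        logger.warning(
            "odorant %r: malformed SMILES %r dropped", odorant_id, smiles
        )
        return None
    return smiles


def load_panel(path: str | Path, smiles_path: str | Path | None = None) -> OdorantPanel:
    """Load an odorant panel from a delimited-text file.

    The file must have a header row with at least ``id``, ``name`` and
    ``class`` columns; optional columns are ``smiles``, ``vapor_pressure_pa``,
    ``liquid_mole_fraction`` and ``conc_molar``.  Comma or tab delimiters are
    sniffed from the header.  SMILES may alternatively be supplied through a
    sidecar ``.smi`` file with one ``SMILES<whitespace>id`` record per line.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    required = {"id", "name", "class"}
    missing = required - set(reader.fieldnames or [])
    if missing:
        raise PanelValidationError(f"panel file missing columns: {sorted(missing)}")

    smi_lookup: dict[str, str] = {}
    if smiles_path is not None:
        for line in Path(smiles_path).read_text(encoding="utf-8").splitlines():
            parts = line.split()
            if len(parts) >= 2:
                smi_lookup[parts[1]] = parts[0]

    def _float(row: dict, key: str) -> float | None:
        raw = (row.get(key) or "").strip()
        return float(raw) if raw else None

    odorants = []
    for row in reader:
        oid = row["id"].strip()
        smiles = (row.get("smiles") or "").strip() or smi_lookup.get(oid) or None
        if smiles is not None:
            smiles = _validate_smiles(smiles, oid)
        odorants.append(
            Odorant(
                id=oid,
                name=row["name"].strip(),
                structural_class=row["class"].strip() or MIXED,
                smiles=smiles,
                vapor_pressure=_float(row, "vapor_pressure_pa"),
                liquid_mole_fraction=_float(row, "liquid_mole_fraction"),
                est_concentration=_float(row, "conc_molar"),
            )
        )
    return OdorantPanel(odorants)


def write_panel(panel: OdorantPanel, path: str | Path) -> None:
    """Write a panel back to the delimited-text layout ``load_panel`` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["id", "name", "class", "smiles", "vapor_pressure_pa",
             "liquid_mole_fraction", "conc_molar"]
        )
        for o in panel:
            writer.writerow(
                [o.id, o.name, o.structural_class, o.smiles or "",
                 "" if o.vapor_pressure is None else repr(o.vapor_pressure),
                 "" if o.liquid_mole_fraction is None else repr(o.liquid_mole_fraction),
                 "" if o.est_concentration is None else repr(o.est_concentration)]
            )


def estimate_vapor_concentration(
    vapor_pressure: float,
    liquid_mole_fraction: float,
    olfactometer_dilution: float = 1.0,
    T: float = T_DEFAULT,
    P_atm: float = P_ATM_DEFAULT,
) -> float:
    """Estimate delivered vapor-phase concentration (mol/L) under Raoult's law.

    The odorant's headspace partial pressure is
    ``liquid_mole_fraction * vapor_pressure``; dividing by RT gives the
    headspace molarity, which the olfactometer further dilutes into the
    carrier stream by ``olfactometer_dilution`` (a single calibrated scalar).
    """
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    for name, v in (
        ("vapor_pressure", vapor_pressure),
        ("liquid_mole_fraction", liquid_mole_fraction),
        ("olfactometer_dilution", olfactometer_dilution),
        ("P_atm", P_atm),
    ):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if liquid_mole_fraction > 1:
        raise ValueError("liquid_mole_fraction must be <= 1")
    partial_pressure = liquid_mole_fraction * vapor_pressure  # Pa
    molar_m3 = partial_pressure / (R_GAS * T)  # mol/m^3
    return molar_m3 / 1000.0 * olfactometer_dilution  # mol/L


def molar_to_ppb(
    conc: float, T: float = T_DEFAULT, P_atm: float = P_ATM_DEFAULT
) -> float:
    """Convert a vapor-phase molarity (mol/L) to ppb by mole fraction."""
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    total_molar = P_atm / (R_GAS * T) / 1000.0  # mol/L of gas at T, P
    return conc / total_molar * 1e9


def ppb_to_molar(
    ppb: float, T: float = T_DEFAULT, P_atm: float = P_ATM_DEFAULT
) -> float:
    """Inverse of :func:`molar_to_ppb`."""
    if ppb < 0:
        raise ValueError("ppb must be nonnegative")
    total_molar = P_atm / (R_GAS * T) / 1000.0
    return ppb / 1e9 * total_molar


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant digits (reported-concentration precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
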