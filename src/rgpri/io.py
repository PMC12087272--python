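"""Reading, validation and normalization of charge, energy and reaction tables.

The toolkit consumes three flat delimited tables (comma or tab, UTF-8):

``charges``
    One row per (molecule, electronic state, atom):
    ``molecule_id,state,atom_index,element,charge[,site_label,attached_to]``.
    ``state`` is one of ``N``, ``N-1``, ``N+1`` (the neutral-reference,
    electron-removed and electron-added single points evaluated at the same
    geometry).  ``attached_to`` maps a hydrogen to the heavy atom whose
    condensed site it belongs to.

``energies``
    One row per species: ``species_id,E_N,E_N_minus_1,E_N_plus_1`` in any
    single consistent energy unit.

``reactions``
    One row per (molecule, radical, site):
    ``molecule_id,radical_id,site_label,dH,ey``.  ``dH`` is the activation
    enthalpy in kJ/mol; ``ey`` the experimental yield ratio.  A ``-`` (or
    empty) cell means the quantity is absent; a literal ``0`` is kept as the
    number zero, which is distinct from absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATE_TAGS = ("N", "N-1", "N+1")

#: Charge (in units of e) added to the neutral-reference molecular charge for
#: each electronic state: removing an electron (N-1) adds +1, adding one (N+1)
#: adds -1.
_STATE_CHARGE_OFFSET = {"N": 0, "N-1": +1, "N+1": -1}

#: Single-bond covalent radii in angstrom (Cordero et al. consensus values),
#: used only by :func:`infer_attachments`.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


class TableError(ValueError):
    """A table could not be parsed or failed validation."""


@dataclass(frozen=True)
class AtomEntry:
    """One atom of a molecule.

    ``atom_index`` is 1-based, matching quantum-chemistry output conventions.
    ``site_label`` names the condensed reactive site (``C2`` .. ``C6`` for the
    heteroarene ring carbons); ``attached_to`` is set only for hydrogens and
    points at the heavy atom that absorbs their charge.
    """

    atom_index: int
    element: str
    site_label: str | None = None
    attached_to: int | None = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class ChargeState:
    """Per-atom partial charges of one electronic state (units of e)."""

    state_tag: str
    charges: dict[int, float]

    def total(self) -> float:
        return float(sum(self.charges.values()))


@dataclass(frozen=True)
class MoleculeChargeSet:
    """Charges of one species in the N, N-1 and N+1 electron states."""

    molecule_id: str
    atoms: tuple[AtomEntry, ...]
    states: dict[str, ChargeState]
    net_charge_N: int = 0

    def __post_init__(self):
        # canonical atom order: ascending 1-based index
        object.__setattr__(self, "atoms",
                           tuple(sorted(self.atoms, key=lambda a: a.atom_index)))
        if set(self.states) != set(STATE_TAGS):
            missing = sorted(set(STATE_TAGS) - set(self.states))
            raise TableError(
                f"molecule {self.molecule_id!r}: missing state(s) {missing}"
            )
        idx = {a.atom_index for a in self.atoms}
        if len(idx) != len(self.atoms):
            raise TableError(f"molecule {self.molecule_id!r}: duplicate atom_index")
        for st in self.states.values():
            if set(st.charges) != idx:
                raise TableError(
                    f"molecule {self.molecule_id!r}: state {st.state_tag!r} does "
                    f"not cover the same atom set as the atom list"
                )
        labels = [a.site_label for a in self.atoms if a.site_label]
        if len(labels) != len(set(labels)):
            raise TableError(f"molecule {self.molecule_id!r}: duplicate site_label")
        by_index = {a.atom_index: a for a in self.atoms}
        for a in self.atoms:
            if a.attached_to is not None:
                if not a.is_hydrogen:
                    raise TableError(
                        f"molecule {self.molecule_id!r}: atom {a.atom_index} is not "
                        f"a hydrogen but has attached_to set"
                    )
                target = by_index.get(a.attached_to)
                if target is None or target.is_hydrogen:
                    raise TableError(
                        f"molecule {self.molecule_id!r}: hydrogen {a.atom_index} "
                        f"attached_to {a.attached_to} is not a heavy atom of the "
                        f"molecule"
                    )

    def atom(self, atom_index: int) -> AtomEntry:
        return next(a for a in self.atoms if a.atom_index == atom_index)

    def expected_total(self, state_tag: str) -> int:
        return self.net_charge_N + _STATE_CHARGE_OFFSET[state_tag]

    def validate_charge_sums(self, tol: float = 1e-3) -> None:
        """Check that each state's charges sum to the state's net charge."""
        for tag in STATE_TAGS:
            dev = self.states[tag].total() - self.expected_total(tag)
            if abs(dev) > tol:
                raise TableError(
                    f"molecule {self.molecule_id!r}: state {tag!r} charges sum to "
                    f"{self.states[tag].total():.6f}, expected "
                    f"{self.expected_total(tag)} (deviation {dev:+.6f} > tol {tol})"
                )


@dataclass(frozen=True)
class EnergyTriple:
    """Total energies of one species in the three electron states."""

    species_id: str
    E_N: float
    E_N_minus_1: float
    E_N_plus_1: float

    def __post_init__(self):
        for name in ("E_N", "E_N_minus_1", "E_N_plus_1"):
            if not math.isfinite(getattr(self, name)):
                raise TableError(f"species {self.species_id!r}: {name} is not finite")


@dataclass(frozen=True)
class ReactionData:
    """Reference data for one molecule-radical pair.

    ``dH`` maps site label to the activation enthalpy of radical addition at
    that site (kJ/mol).  ``ey`` maps site label to the experimental yield
    ratio; a site absent from ``ey`` means no product was isolated there,
    which is distinct from an isolated product recorded with ratio 0.
    """

    molecule_id: str
    radical_id: str
    dH: dict[str, float] = field(default_factory=dict)
    ey: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for site, v in self.dH.items():
            if not v > 0:
                raise TableError(
                    f"reaction {self.molecule_id}+{self.radical_id}: dH at "
                    f"{site} must be positive, got {v}"
                )
        for site, v in self.ey.items():
            if v < 0:
                raise TableError(
                    f"reaction {self.molecule_id}+{self.radical_id}: ey at "
                    f"{site} must be >= 0, got {v}"
                )


# ---------------------------------------------------------------------------
# table loading


def _read_table(path, required: set[str], optional: set[str] = frozenset()) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing required column(s) {sorted(missing)}")
    unknown = set(df.columns) - required - optional
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, sorted(unknown))
    return df


def _as_float(raw, where: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise TableError(f"{where}: cannot parse {raw!r} as a number") from None


def load_charge_table(path, *, net_charges=0, charge_sum_tol: float = 1e-3,
                      validate_sums: bool = True) -> list[MoleculeChargeSet]:
    """Read a three-state charge table into :class:`MoleculeChargeSet` records.

    Parameters
    ----------
    net_charges : int or mapping
        Net charge of the N-electron state, either one integer for all
        molecules or a mapping ``molecule_id -> int``.
    charge_sum_tol : float
        Tolerance (in e) for the per-state charge-sum check.
    """
    df = _read_table(path, {"molecule_id", "state", "atom_index", "element",
                            "charge"}, {"site_label", "attached_to"})
    out = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        states_present = set(grp["state"])
        bad = states_present - set(STATE_TAGS)
        if bad:
            raise TableError(f"molecule {mol_id!r}: unknown state tag(s) {sorted(bad)}")
        missing = set(STATE_TAGS) - states_present
        if missing:
            raise TableError(f"molecule {mol_id!r}: missing state {sorted(missing)}")
        seen = set()
        atoms: dict[int, AtomEntry] = {}
        charges: dict[str, dict[int, float]] = {t: {} for t in STATE_TAGS}
        for _, row in grp.iterrows():
            idx = int(row["atom_index"])
            key = (row["state"], idx)
            if key in seen:
                raise TableError(
                    f"molecule {mol_id!r}: duplicate (state, atom_index) "
                    f"({row['state']!r}, {idx})"
                )
            seen.add(key)
            charges[row["state"]][idx] = _as_float(
                row["charge"], f"molecule {mol_id!r} atom {idx}")
            site = row.get("site_label")
            site = None if (site is None or pd.isna(site) or site == "") else str(site)
            att = row.get("attached_to")
            att = None if (att is None or pd.isna(att) or att == "") else int(float(att))
            entry = AtomEntry(idx, str(row["element"]).strip(), site, att)
            if idx in atoms and atoms[idx] != entry:
                raise TableError(
                    f"molecule {mol_id!r}: atom {idx} has inconsistent metadata "
                    f"across state rows"
                )
            atoms[idx] = entry
        net = net_charges[mol_id] if isinstance(net_charges, dict) else int(net_charges)
        mcs = MoleculeChargeSet(
            molecule_id=str(mol_id),
            atoms=tuple(atoms[i] for i in sorted(atoms)),
            states={t: ChargeState(t, charges[t]) for t in STATE_TAGS},
            net_charge_N=net,
        )
        if validate_sums:
            mcs.validate_charge_sums(charge_sum_tol)
        out.append(mcs)
    return out


def write_charge_table(mcs_list, path) -> None:
    """Write charge sets in the normalized dialect read by :func:`load_charge_table`."""
    rows = []
    for mcs in mcs_list:
        for tag in STATE_TAGS:
            for a in mcs.atoms:
                rows.append({
                    "molecule_id": mcs.molecule_id,
                    "state": tag,
                    "atom_index": a.atom_index,
                    "element": a.element,
                    "charge": repr(float(mcs.states[tag].charges[a.atom_index])),
                    "site_label": a.site_label or "",
                    "attached_to": "" if a.attached_to is None else a.attached_to,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_energy_table(path) -> list[EnergyTriple]:
    df = _read_table(path, {"species_id", "E_N", "E_N_minus_1", "E_N_plus_1"})
    out = []
    for _, row in df.iterrows():
        sid = str(row["species_id"])
        vals = {}
        for col in ("E_N", "E_N_minus_1", "E_N_plus_1"):
            raw = row[col]
            if raw is None or pd.isna(raw) or str(raw).strip() == "":
                raise TableError(f"species {sid!r}: missing {col}")
            vals[col] = _as_float(raw, f"species {sid!r} column {col}")
        out.append(EnergyTriple(sid, **vals))
    return out


def write_energy_table(triples, path) -> None:
    pd.DataFrame([
        {"species_id": t.species_id, "E_N": repr(float(t.E_N)),
         "E_N_minus_1": repr(float(t.E_N_minus_1)),
         "E_N_plus_1": repr(float(t.E_N_plus_1))}
        for t in triples
    ]).to_csv(path, index=False)


#: Cell values understood as "absent" in reaction tables ("-" as printed in
#: yield tables, the unicode minus, or an empty cell).
_ABSENT = {"-", "−", ""}


def _absent(raw) -> bool:
    return raw is None or (isinstance(raw, float) and math.isnan(raw)) \
        or str(raw).strip() in _ABSENT


def load_reaction_table(path) -> list[ReactionData]:
    """Read per-site activation enthalpies and experimental yield ratios."""
    df = _read_table(path, {"molecule_id", "radical_id", "site_label", "dH", "ey"})
    out = []
    for (mol, rad), grp in df.groupby(["molecule_id", "radical_id"], sort=True):
        dH: dict[str, float] = {}
        ey: dict[str, float] = {}
        for _, row in grp.iterrows():
            site = str(row["site_label"]).strip()
            where = f"reaction {mol}+{rad} site {site}"
            if site in dH or (site in ey):
                raise TableError(f"{where}: duplicate site row")
            if not _absent(row["dH"]):
                dH[site] = _as_float(row["dH"], where)
            if not _absent(row["ey"]):
                ey[site] = _as_float(row["ey"], where)
        out.append(ReactionData(str(mol), str(rad), dH, ey))
    return out


def write_reaction_table(reactions, path) -> None:
    rows = []
    for rd in reactions:
        for site in sorted(set(rd.dH) | set(rd.ey)):
            rows.append({
                "molecule_id": rd.molecule_id, "radical_id": rd.radical_id,
                "site_label": site,
                "dH": "-" if site not in rd.dH else repr(float(rd.dH[site])),
                "ey": "-" if site not in rd.ey else repr(float(rd.ey[site])),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# hydrogen handling


def sum_hydrogens(mcs: MoleculeChargeSet) -> MoleculeChargeSet:
    """Fold each hydrogen's charge into its attached heavy atom, per state.

    Returns a charge set containing only heavy atoms; the per-state total
    charge is conserved exactly.  Idempotent on hydrogen-free inputs.
    """
    hydrogens = [a for a in mcs.atoms if a.is_hydrogen]
    if not hydrogens:
        return mcs
    for h in hydrogens:
        if h.attached_to is None:
            raise TableError(
                f"molecule {mcs.molecule_id!r}: hydrogen {h.atom_index} has no "
                f"attached_to mapping; set it explicitly or run infer_attachments"
            )
    heavy = tuple(a for a in mcs.atoms if not a.is_hydrogen)
    new_states = {}
    for tag in STATE_TAGS:
        q = dict(mcs.states[tag].charges)
        for h in hydrogens:
            q[h.attached_to] += q.pop(h.atom_index)
        new_states[tag] = ChargeState(tag, q)
    return MoleculeChargeSet(mcs.molecule_id, heavy, new_states, mcs.net_charge_N)


def read_xyz(path):
    """Read a plain XYZ file -> (list of element symbols, (n, 3) coordinates)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise TableError(f"{path}: first line of an XYZ file must be the atom count")
    body = lines[2:2 + n]
    if len(body) != n:
        raise TableError(f"{path}: expected {n} atom lines, found {len(body)}")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.asarray(coords, dtype=float)


def infer_attachments(mcs: MoleculeChargeSet, coords,
                      scale: float = 1.2) -> MoleculeChargeSet:
    """Assign each unmapped hydrogen to its nearest heavy atom.

    ``coords`` maps atom_index to a 3-vector (or is an (n_atoms, 3) array in
    atom order).  A hydrogen is attached when the distance is below
    ``scale * (r_cov(H) + r_cov(X))``; an exact distance tie between two heavy
    atoms is rejected so an ambiguous geometry must be mapped explicitly.
    Explicit ``attached_to`` values are never overwritten.
    """
    if not isinstance(coords, dict):
        arr = np.asarray(coords, dtype=float)
        if arr.shape != (len(mcs.atoms), 3):
            raise TableError(
                f"molecule {mcs.molecule_id!r}: coordinates shape {arr.shape} "
                f"does not match {len(mcs.atoms)} atoms"
            )
        coords = {a.atom_index: arr[i] for i, a in enumerate(mcs.atoms)}
    for a in mcs.atoms:
        if a.atom_index not in coords:
            raise TableError(
                f"molecule {mcs.molecule_id!r}: no coordinates for atom {a.atom_index}"
            )
    heavy = [a for a in mcs.atoms if not a.is_hydrogen]
    new_atoms = []
    for a in mcs.atoms:
        if not a.is_hydrogen or a.attached_to is not None:
            new_atoms.append(a)
            continue
        pos = np.asarray(coords[a.atom_index], dtype=float)
        dists = np.array([
            np.linalg.norm(pos - np.asarray(coords[h.atom_index], dtype=float))
            for h in heavy
        ])
        order = np.argsort(dists)
        best = heavy[order[0]]
        d = dists[order[0]]
        if len(heavy) > 1 and dists[order[1]] == d:
            raise TableError(
                f"molecule {mcs.molecule_id!r}: hydrogen {a.atom_index} is "
                f"equidistant from atoms {best.atom_index} and "
                f"{heavy[order[1]].atom_index}; provide attached_to explicitly"
            )
        try:
            cutoff = scale * (COVALENT_RADII["H"] + COVALENT_RADII[best.element])
        except KeyError:
            raise TableError(
                f"molecule {mcs.molecule_id!r}: no covalent radius for element "
                f"{best.element!r}"
            ) from None
        if d >= cutoff:
            raise TableError(
                f"molecule {mcs.molecule_id!r}: hydrogen {a.atom_index} is "
                f"{d:.2f} A from the nearest heavy atom {best.atom_index} "
                f"(cutoff {cutoff:.2f} A); not bonded"
            )
        new_atoms.append(replace(a, attached_to=best.atom_index))
    return MoleculeChargeSet(mcs.molecule_id, tuple(new_atoms), mcs.states,
                             mcs.net_charge_N)
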