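"""Conceptual-DFT descriptors: condensed Fukui functions, Mulliken
electronegativity and the electrophilic/nucleophilic classification of an
attacking radical.

The condensed Fukui functions are finite-difference derivatives of the
electron density with respect to electron number, projected onto atoms by a
population scheme.  With per-atom charges q(N), q(N-1), q(N+1) taken at the
same geometry:

    f-  = q(N-1) - q(N)      (electrophilic attack)
    f+  = q(N)   - q(N+1)    (nucleophilic attack)
    f0  = (f- + f+) / 2      (radical attack; the "RFF")

When the three state charges sum to the molecular charge, its charge +1 and
its charge -1, each of f-, f+ and f0 sums to exactly 1 over all atoms of the
molecule.

The Mulliken electronegativity chi = (I + A)/2 with I = E(N-1) - E(N) and
A = E(N) - E(N+1) measures the tendency of a species to gain electrons;
comparing chi of the radical and of the substrate decides whether the radical
accepts electrons (electrophilic radical) or donates them (nucleophilic
radical), and therefore which reactivity-indicator equation applies to the
substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import EnergyTriple, MoleculeChargeSet

logger = logging.getLogger(__name__)

ELECTROPHILIC_RADICAL = "electrophilic_radical"
NUCLEOPHILIC_RADICAL = "nucleophilic_radical"


@dataclass(frozen=True)
class SiteDescriptors:
    """Condensed descriptors of one site: ground-state charge and Fukui values."""

    q0: float
    f_minus: float
    f_plus: float
    f_zero: float


@dataclass(frozen=True)
class CondensedSiteSet:
    """Per-site condensed descriptors of one molecule.

    ``sites`` holds only the reported sites (e.g. the C2-C6 ring carbons when
    a restriction was requested); the ``sum_*`` attributes are totals over all
    atoms the computation saw, which is what the sum-to-one normalization
    applies to.
    """

    molecule_id: str
    sites: dict[str, SiteDescriptors]
    sum_f_minus: float
    sum_f_plus: float

    @property
    def sum_f_zero(self) -> float:
        return 0.5 * (self.sum_f_minus + self.sum_f_plus)

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(self.sites)

    def q0(self, site: str) -> float:
        return self.sites[site].q0

    def f_zero(self, site: str) -> float:
        return self.sites[site].f_zero

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"site": s, "q0": d.q0, "f_minus": d.f_minus,
              "f_plus": d.f_plus, "f_zero": d.f_zero}
             for s, d in self.sites.items()]
        )


@dataclass(frozen=True)
class ElectronegativityResult:
    species_id: str
    I: float
    A: float
    chi: float


@dataclass(frozen=True)
class RadicalRole:
    """Outcome of the electronegativity comparison for one reactant pair."""

    radical_id: str
    molecule_id: str
    role: str
    chi_radical: float
    chi_molecule: float


def site_key(atom) -> str:
    """Public key of an atom in descriptor reports: its site label if given,
    otherwise element symbol + 1-based index (e.g. ``N1``)."""
    return atom.site_label or f"{atom.element}{atom.atom_index}"


def condensed_fukui(mcs: MoleculeChargeSet,
                    restrict_to=None) -> CondensedSiteSet:
    """Condensed Fukui functions of every atom of ``mcs``.

    ``mcs`` should normally be hydrogen-summed first so ring C-H units are
    condensed into their carbons.  ``restrict_to`` filters which sites are
    *reported*; the computation (and the sum-to-one totals) always run over
    all atoms, since the normalization only holds molecule-wide.
    """
    f_minus, f_plus, q0 = {}, {}, {}
    qN = mcs.states["N"].charges
    qNm1 = mcs.states["N-1"].charges
    qNp1 = mcs.states["N+1"].charges
    for a in mcs.atoms:
        key = site_key(a)
        i = a.atom_index
        q0[key] = qN[i]
        f_minus[key] = qNm1[i] - qN[i]
        f_plus[key] = qN[i] - qNp1[i]
    sum_fm = float(sum(f_minus.values()))
    sum_fp = float(sum(f_plus.values()))
    if restrict_to is None:
        keys = list(q0)
    else:
        keys = list(restrict_to)
        missing = [k for k in keys if k not in q0]
        if missing:
            raise KeyError(
                f"molecule {mcs.molecule_id!r}: site(s) {missing} not found; "
                f"available: {sorted(q0)}"
            )
    sites = {
        k: SiteDescriptors(
            q0=q0[k], f_minus=f_minus[k], f_plus=f_plus[k],
            f_zero=0.5 * (f_minus[k] + f_plus[k]),
        )
        for k in keys
    }
    return CondensedSiteSet(mcs.molecule_id, sites, sum_fm, sum_fp)


def electronegativity(et: EnergyTriple) -> ElectronegativityResult:
    """Mulliken electronegativity from vertical total-energy differences."""
    I = et.E_N_minus_1 - et.E_N
    A = et.E_N - et.E_N_plus_1
    if A < 0:
        logger.warning("species %s: negative electron affinity A=%g", et.species_id, A)
    return ElectronegativityResult(et.species_id, I=I, A=A, chi=0.5 * (I + A))


def classify_radical(chi_molecule: ElectronegativityResult,
                     chi_radical: ElectronegativityResult) -> RadicalRole:
    """Classify the radical relative to the substrate by electronegativity.

    chi_molecule < chi_radical: the radical gains electrons (electrophilic
    radical; the substrate is treated as the nucleophile-like partner).
    chi_molecule > chi_radical: the radical donates electrons (nucleophilic
    radical).  Exact equality carries no decision and is an error; pass an
    explicit role downstream if the data genuinely ties.
    """
    if chi_molecule.chi == chi_radical.chi:
        raise ValueError(
            f"electronegativity tie between {chi_molecule.species_id!r} and "
            f"{chi_radical.species_id!r} (chi={chi_molecule.chi!r}); supply the "
            f"radical role explicitly"
        )
    role = (ELECTROPHILIC_RADICAL if chi_molecule.chi < chi_radical.chi
            else NUCLEOPHILIC_RADICAL)
    return RadicalRole(
        radical_id=chi_radical.species_id,
        molecule_id=chi_molecule.species_id,
        role=role,
        chi_radical=chi_radical.chi,
        chi_molecule=chi_molecule.chi,
    )
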