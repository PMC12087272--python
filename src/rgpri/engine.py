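"""The radical general-purpose reactivity indicator (R-GPRI) engine.

For a site alpha with condensed ground-state charge q0 and condensed radical
Fukui function f0 the indicator is

    eq1 (nucleophile-like substrate, electrophilic radical attack):
        Xi = (kappa + 1) * q0 - dN * (kappa - 1) * f0
    eq2 (electrophile-like substrate, nucleophilic radical attack):
        Xi = -(kappa + 1) * q0 + dN * (kappa - 1) * f0

where kappa weighs charge control (kappa ~ +1) against electron-transfer
control (kappa ~ -1) and dN is the signed extent of electron transfer.  At
each (kappa, dN) grid point the site with the smallest Xi is the predicted
most reactive site ("first choice") and the second smallest the second most
reactive.  The grid of choices is a reactivity transition table (RTT); a
majority vote over a region of the RTT yields the site prediction for the
reaction regime that region models:

    black box (electron transfer, e-T):   kappa in [-1.0, -0.4]
    pink box (strong electron transfer):  kappa in [-1.4, -1.2]
    ERRC:                                 black + pink

with dN in [-0.8, 0.2] for electrophilic radical attack and [-0.2, 0.8] for
nucleophilic radical attack (default grid step 0.2 in both parameters).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .cdft import (ELECTROPHILIC_RADICAL, NUCLEOPHILIC_RADICAL,
                   CondensedSiteSet, RadicalRole)

EQ1 = "eq1"
EQ2 = "eq2"

BLACK = "black_eT"
PINK = "pink_SeT"
ERRC = "errc"

#: Resolution used to group floating Xi values into exact-tie sets.
XI_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class GpriParams:
    kappa: float
    delta_n: float


@dataclass(frozen=True)
class RttCell:
    """One (kappa, dN) grid point: Xi per site plus ranked choice sets.

    Choices are sets so that exact Xi ties credit every tied site.
    ``second_choice`` is empty in the degenerate case where all sites tie.
    """

    params: GpriParams
    xi_by_site: dict[str, float]
    first_choice: frozenset[str]
    second_choice: frozenset[str]


@dataclass(frozen=True)
class Rtt:
    molecule_id: str
    radical_id: str
    equation_used: str
    kappas: tuple[float, ...]
    delta_ns: tuple[float, ...]
    cells: dict[tuple[float, float], RttCell]

    def to_frame(self, rank: str = "first"):
        """Grid as a DataFrame (kappa rows, dN columns, site labels as cells),
        mirroring the layout of published reactivity transition tables."""
        import pandas as pd

        attr = "first_choice" if rank == "first" else "second_choice"
        data = {
            dn: ["/".join(sorted(getattr(self.cells[(k, dn)], attr)))
                 for k in self.kappas]
            for dn in self.delta_ns
        }
        return pd.DataFrame(data, index=pd.Index(self.kappas, name="kappa"))


@dataclass(frozen=True)
class RegionSpec:
    """A named region of the RTT: a union of (kappa, dN) boxes.

    Boxes are (kappa_range, delta_n_range) pairs with ranges normalized to
    (min, max); bounds are inclusive.
    """

    name: str
    boxes: tuple[tuple[tuple[float, float], tuple[float, float]], ...]

    def contains(self, params: GpriParams, atol: float = 1e-9) -> bool:
        for (klo, khi), (dlo, dhi) in self.boxes:
            if (klo - atol <= params.kappa <= khi + atol
                    and dlo - atol <= params.delta_n <= dhi + atol):
                return True
        return False


@dataclass(frozen=True)
class RegionVote:
    region: RegionSpec
    n_cells: int
    first_counts: dict[str, int]
    second_counts: dict[str, int]
    predicted_first: frozenset[str]
    predicted_second: frozenset[str]
    appears_first: frozenset[str]
    appears_second: frozenset[str]


@dataclass(frozen=True)
class GridSpec:
    """The (kappa, dN) values an RTT is evaluated at."""

    kappas: tuple[float, ...]
    delta_ns: tuple[float, ...]


def _span(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(round(lo + i * step, 10) for i in range(n + 1))


def _normalize(rng) -> tuple[float, float]:
    a, b = rng
    return (a, b) if a <= b else (b, a)


#: dN window per radical role, as used for neutral substrates: the printed
#: bounds extend past the nominal sign range of dN on purpose.
DELTA_N_BOUNDS = {
    ELECTROPHILIC_RADICAL: (-0.8, 0.2),
    NUCLEOPHILIC_RADICAL: (-0.2, 0.8),
}

KAPPA_BLACK = (-1.0, -0.4)
KAPPA_PINK = (-1.4, -1.2)


def default_regions(role: str, *, mirror_delta_n: bool = False) -> dict[str, RegionSpec]:
    """The black / pink / ERRC regions for a radical role.

    ``mirror_delta_n`` flips the dN window to the opposite role's bounds
    (a config switch for exploring the alternative reading of the window).
    """
    lookup_role = role
    if mirror_delta_n:
        lookup_role = (NUCLEOPHILIC_RADICAL if role == ELECTROPHILIC_RADICAL
                       else ELECTROPHILIC_RADICAL)
    dn = _normalize(DELTA_N_BOUNDS[lookup_role])
    black = RegionSpec(BLACK, ((KAPPA_BLACK, dn),))
    pink = RegionSpec(PINK, ((KAPPA_PINK, dn),))
    errc = RegionSpec(ERRC, (black.boxes[0], pink.boxes[0]))
    return {BLACK: black, PINK: pink, ERRC: errc}


def default_grid(role: str, step: float = 0.2, *,
                 mirror_delta_n: bool = False) -> GridSpec:
    """Default RTT grid: the kappa span of black+pink boxes crossed with the
    role's dN window, inclusive endpoints."""
    lookup_role = role
    if mirror_delta_n:
        lookup_role = (NUCLEOPHILIC_RADICAL if role == ELECTROPHILIC_RADICAL
                       else ELECTROPHILIC_RADICAL)
    dlo, dhi = _normalize(DELTA_N_BOUNDS[lookup_role])
    return GridSpec(
        kappas=_span(KAPPA_PINK[0], KAPPA_BLACK[1], step),
        delta_ns=_span(dlo, dhi, step),
    )


def equation_for_role(role) -> str:
    r = role.role if isinstance(role, RadicalRole) else role
    if r == ELECTROPHILIC_RADICAL:
        return EQ1
    if r == NUCLEOPHILIC_RADICAL:
        return EQ2
    raise ValueError(f"unknown radical role {r!r}")


def gpri_value(q0: float, f0: float, params: GpriParams, equation: str) -> float:
    """Xi of one site at one (kappa, dN) point."""
    term_q = (params.kappa + 1.0) * q0
    term_f = params.delta_n * (params.kappa - 1.0) * f0
    if equation == EQ1:
        return term_q - term_f
    if equation == EQ2:
        return -term_q + term_f
    raise ValueError(f"unknown equation {equation!r}")


def rank_levels(values: dict[str, float], atol: float = XI_TIE_ATOL):
    """Group sites into ascending tie levels of their values.

    Returns a list of frozensets, best (smallest) first; sites whose values
    differ by at most ``atol`` share a level.
    """
    order = sorted(values, key=lambda s: (values[s], s))
    levels: list[list[str]] = []
    for s in order:
        if levels and abs(values[s] - values[levels[-1][0]]) <= atol:
            levels[-1].append(s)
        else:
            levels.append([s])
    return [frozenset(level) for level in levels]


def build_rtt(css: CondensedSiteSet, role, grid: GridSpec | None = None,
              *, radical_id: str | None = None) -> Rtt:
    """Evaluate Xi for every site at every grid point and rank the sites.

    ``role`` is a :class:`~rgpri.cdft.RadicalRole` (or role string); it picks
    the equation: electrophilic radical -> eq1 on the substrate, nucleophilic
    radical -> eq2.
    """
    if len(css.sites) < 2:
        raise ValueError(
            f"molecule {css.molecule_id!r}: an RTT needs at least two sites "
            f"(second choice undefined otherwise)"
        )
    equation = equation_for_role(role)
    role_str = role.role if isinstance(role, RadicalRole) else role
    if grid is None:
        grid = default_grid(role_str)
    if radical_id is None:
        radical_id = role.radical_id if isinstance(role, RadicalRole) else ""
    cells = {}
    for k in grid.kappas:
        for dn in grid.delta_ns:
            params = GpriParams(k, dn)
            xi = {s: gpri_value(d.q0, d.f_zero, params, equation)
                  for s, d in css.sites.items()}
            levels = rank_levels(xi)
            cells[(k, dn)] = RttCell(
                params=params,
                xi_by_site=xi,
                first_choice=levels[0],
                second_choice=levels[1] if len(levels) > 1 else frozenset(),
            )
    return Rtt(css.molecule_id, radical_id, equation, grid.kappas,
               grid.delta_ns, cells)


def _argmax_set(counts: Counter) -> frozenset[str]:
    if not counts:
        return frozenset()
    top = max(counts.values())
    return frozenset(s for s, c in counts.items() if c == top)


def region_vote(rtt: Rtt, region: RegionSpec) -> RegionVote:
    """Tally first/second choices over the region's cells.

    Vote ties are reported as sets, never broken; each member of a tied
    per-cell choice receives one count.  A cell whose first-choice tie spans
    every site discriminates nothing (the indicator is constant there, e.g.
    at exactly kappa = -1, dN = 0 where both terms vanish) and is left out of
    the tally; ``n_cells`` counts tallied cells only.
    """
    first: Counter = Counter()
    second: Counter = Counter()
    n_cells = 0
    for cell in rtt.cells.values():
        if not region.contains(cell.params):
            continue
        if len(cell.first_choice) == len(cell.xi_by_site):
            continue
        n_cells += 1
        for s in cell.first_choice:
            first[s] += 1
        for s in cell.second_choice:
            second[s] += 1
    if n_cells == 0:
        raise ValueError(f"region {region.name!r} covers no cell of the RTT")
    return RegionVote(
        region=region,
        n_cells=n_cells,
        first_counts=dict(first),
        second_counts=dict(second),
        predicted_first=_argmax_set(first),
        predicted_second=_argmax_set(second),
        appears_first=frozenset(first),
        appears_second=frozenset(second),
    )


def predict_sites(css: CondensedSiteSet, role, grid: GridSpec | None = None,
                  regions=None) -> dict[str, RegionVote]:
    """RTT construction + region votes over black, pink and ERRC.

    Returns ``{region name: RegionVote}``; each vote carries the predicted
    first/second site sets and the appears-in-at-least-one-cell sets used by
    the "!" verdict downstream.
    """
    role_str = role.role if isinstance(role, RadicalRole) else role
    if regions is None:
        regions = default_regions(role_str)
    rtt = build_rtt(css, role, grid)
    return {name: region_vote(rtt, spec) for name, spec in regions.items()}


def rff_predict(css: CondensedSiteSet) -> list[frozenset[str]]:
    """Rank sites by descending condensed radical Fukui function.

    Returns tie levels, most reactive first; exact f0 ties are grouped.
    """
    if len(css.sites) < 2:
        raise ValueError(
            f"molecule {css.molecule_id!r}: ranking needs at least two sites"
        )
    neg_f0 = {s: -d.f_zero for s, d in css.sites.items()}
    return rank_levels(neg_f0)
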