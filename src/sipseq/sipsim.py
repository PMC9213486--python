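"""Forward simulator of DNA stable-isotope probing (DNA-SIP) experiments.

A DNA-SIP incubation feeds a microbial community a :sup:`13`\\ C-labelled
substrate (here gaseous ethane or propane); organisms that assimilate the
substrate build denser DNA, which is resolved on an isopycnic CsCl gradient
and collected as ordered fractions. This module generates such experiments
in silico with complete ground truth: each taxon is a Gaussian band on the
density axis positioned by its GC content and its :sup:`13`\\ C atom-fraction
excess, fraction DNA masses are Gaussian band integrals, and per-fraction
taxon counts are multinomial sequencing draws.

The defaults mirror a typical gas-seep SIP setup: 1 % (v/v) substrate in the
headspace, duplicate vials per substrate x isotope, and 12 gradient
fractions per vial read out by refractometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Taxon",
    "GradientParams",
    "SIPDesign",
    "CommunityProfile",
    "SIPDataset",
    "taxon_density",
    "simulate_fractions",
    "simulate_experiment",
    "simulate_headspace",
    "default_community",
    "write_fraction_table",
    "write_ground_truth",
]

#: Fixed per-taxon columns of a fraction table, in output order.
FRACTION_TABLE_COLUMNS = ["vial_id", "fraction", "refractive_index", "density_g_ml", "dna_ng"]


@dataclass(frozen=True)
class Taxon:
    """One community member with its banding determinants.

    ``atom_excess`` is the :sup:`13`\\ C atom fraction excess of the taxon's
    DNA (0 = natural abundance, 1 = fully labelled). ``consumes`` names the
    substrates this taxon assimilates; in a :sup:`12`\\ C control vial, and
    for every non-consumer, the effective excess is forced to zero.
    """

    id: str
    gc: float
    rel_abundance: float
    atom_excess: float = 0.0
    consumes: frozenset = frozenset()

    def __post_init__(self):
        for name in ("gc", "rel_abundance", "atom_excess"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1] for taxon {self.id!r}")


@dataclass(frozen=True)
class GradientParams:
    """Physics of the CsCl gradient and the refractometer readout.

    Buoyant density of unlabelled DNA follows the Schildkraut affine
    relation rho = 1.660 + 0.098*GC g/ml; full :sup:`13`\\ C labelling adds
    0.036 g/ml. Refractive index is an affine proxy for density,
    rho = ri_slope*RI - ri_intercept.
    """

    n_fractions: int = 12
    density_min: float = 1.698
    density_max: float = 1.752
    band_sigma: float = 0.004
    gc_slope: float = 0.098
    gc_intercept: float = 1.660
    full_label_shift: float = 0.036
    ri_slope: float = 10.9276
    ri_intercept: float = 13.593

    def __post_init__(self):
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not self.density_min < self.density_max:
            raise ValueError("density_min must be < density_max")
        if not self.band_sigma > 0:
            raise ValueError("band_sigma must be > 0")
        if self.full_label_shift < 0:
            raise ValueError("full_label_shift must be >= 0")

    def fraction_edges(self) -> np.ndarray:
        """Equal-width fraction boundaries over [density_min, density_max]."""
        return np.linspace(self.density_min, self.density_max, self.n_fractions + 1)

    def fraction_midpoints(self) -> np.ndarray:
        e = self.fraction_edges()
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class Substrate:
    name: str
    n_carbons: int


@dataclass(frozen=True)
class SIPDesign:
    """Vial layout of a SIP experiment: substrate x isotope x replicate."""

    substrates: tuple = (Substrate("ethane", 2), Substrate("propane", 3))
    isotopes: tuple = ("12C", "13C")
    replicates: int = 2
    depth: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class CommunityProfile:
    """Ground-truth community: taxa plus which taxa consume which substrate."""

    taxa: list

    def __post_init__(self):
        total = sum(t.rel_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, not 1")

    @property
    def ids(self):
        return [t.id for t in self.taxa]

    def consumers_of(self, substrate: str):
        return {t.id for t in self.taxa if substrate in t.consumes}


@dataclass
class SIPDataset:
    """One fraction table per vial plus the per-vial ground-truth labels."""

    fraction_tables: dict  # vial_id -> DataFrame
    truth: pd.DataFrame  # columns: vial_id, substrate, isotope, replicate, taxon, true_label
    design: SIPDesign
    params: GradientParams

    def vials(self):
        return list(self.fraction_tables)


# ---------------------------------------------------------------------------
# Banding physics
# ---------------------------------------------------------------------------

def taxon_density(taxon: Taxon, params: GradientParams) -> float:
    """Equilibrium buoyant density (g/ml) of a taxon's DNA band centre.

    rho = gc_intercept + gc_slope*GC + atom_excess*full_label_shift
    """
    if not 0.0 <= taxon.gc <= 1.0:
        raise ValueError("gc outside [0, 1]")
    if not 0.0 <= taxon.atom_excess <= 1.0:
        raise ValueError("atom_excess outside [0, 1]")
    return params.gc_intercept + params.gc_slope * taxon.gc + taxon.atom_excess * params.full_label_shift


def _band_masses(community, params: GradientParams, total_dna_ng: float) -> np.ndarray:
    """(n_taxa, n_fractions) DNA mass matrix from truncated Gaussian bands.

    Band mass falling outside the gradient range is renormalised into range
    so that per-vial mass is conserved exactly.
    """
    edges = params.fraction_edges()
    masses = np.empty((len(community), params.n_fractions))
    for i, t in enumerate(community):
        centre = taxon_density(t, params)
        cdf = norm.cdf(edges, loc=centre, scale=params.band_sigma)
        in_range = cdf[-1] - cdf[0]
        if in_range <= 0:  # band entirely off-gradient: park all mass in nearest edge fraction
            share = np.zeros(params.n_fractions)
            share[0 if centre < edges[0] else -1] = 1.0
        else:
            share = np.diff(cdf) / in_range
        masses[i] = total_dna_ng * t.rel_abundance * share
    return masses


def simulate_fractions(
    community,
    params: GradientParams,
    depth: int,
    total_dna_ng: float = 500.0,
    seed=0,
    vial_id: str = "vial",
) -> pd.DataFrame:
    """Simulate one centrifuged, fractionated and sequenced gradient.

    Returns a fraction table with one row per fraction, numbered 1 = densest
    (heavy-first collection order), with refractive index, density, DNA mass
    and one count column per taxon. ``depth`` is the total read budget of
    the gradient; each fraction receives ``round(depth * mass_share)`` reads
    drawn multinomially over taxa in proportion to their DNA mass there.
    """
    if not community:
        raise ValueError("community is empty")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    masses = _band_masses(community, params, total_dna_ng)
    frac_mass = masses.sum(axis=0)
    mids = params.fraction_midpoints()
    ri = (mids + params.ri_intercept) / params.ri_slope

    counts = np.zeros_like(masses, dtype=np.int64)
    total_mass = frac_mass.sum()
    for j in range(params.n_fractions):
        n_j = int(round(depth * frac_mass[j] / total_mass)) if total_mass > 0 else 0
        if n_j > 0 and frac_mass[j] > 0:
            counts[:, j] = rng.multinomial(n_j, masses[:, j] / frac_mass[j])

    # fraction 1 = densest
    order = np.argsort(mids)[::-1]
    table = pd.DataFrame(
        {
            "vial_id": vial_id,
            "fraction": np.arange(1, params.n_fractions + 1),
            "refractive_index": ri[order],
            "density_g_ml": mids[order],
            "dna_ng": frac_mass[order],
        }
    )
    for i, t in enumerate(community):
        table[t.id] = counts[i, order]
    return table


# ---------------------------------------------------------------------------
# Whole-experiment simulation
# ---------------------------------------------------------------------------

def _vial_community(community: CommunityProfile, substrate: str, isotope: str):
    """Effective taxa for one vial: excess kept only for 13C-fed consumers."""
    out = []
    for t in community.taxa:
        labelled = isotope == "13C" and substrate in t.consumes
        out.append(dataclasses.replace(t, atom_excess=t.atom_excess if labelled else 0.0))
    return out


def simulate_experiment(
    community: CommunityProfile,
    design: SIPDesign = SIPDesign(),
    params: GradientParams = GradientParams(),
    total_dna_ng: float = 500.0,
) -> SIPDataset:
    """Simulate every vial of a substrate x isotope x replicate design.

    Each vial gets its own RNG stream derived from (seed, substrate,
    isotope, replicate) so any vial is reproducible in isolation. In 12C
    vials every taxon's atom excess is forced to 0; in 13C vials only
    consumers of that vial's substrate keep theirs.
    """
    known = {s.name for s in design.substrates}
    flagged = set().union(*(t.consumes for t in community.taxa)) if community.taxa else set()
    missing = flagged - known
    if missing:
        raise ValueError(f"community flags consumers of substrates absent from design: {sorted(missing)}")

    tables = {}
    truth_rows = []
    for si, sub in enumerate(design.substrates):
        for ii, iso in enumerate(design.isotopes):
            for rep in range(1, design.replicates + 1):
                vial_id = f"{sub.name}_{iso}_rep{rep}"
                stream = np.random.SeedSequence(entropy=design.seed, spawn_key=(si, ii, rep))
                vial_taxa = _vial_community(community, sub.name, iso)
                tables[vial_id] = simulate_fractions(
                    vial_taxa, params, design.depth, total_dna_ng, seed=stream, vial_id=vial_id
                )
                for t in vial_taxa:
                    truth_rows.append(
                        {
                            "vial_id": vial_id,
                            "substrate": sub.name,
                            "isotope": iso,
                            "replicate": rep,
                            "taxon": t.id,
                            "true_label": t.atom_excess > 0,
                        }
                    )
    return SIPDataset(tables, pd.DataFrame(truth_rows), design, params)


def simulate_headspace(
    initial_pct: float,
    rate_umol_per_day: float,
    headspace_ml: float,
    days,
    noise_sd: float = 0.0,
    seed=0,
    temperature_K: float = 298.15,
    pressure_kPa: float = 101.325,
) -> pd.DataFrame:
    """Headspace gas-chromatography time series under linear consumption.

    The expected % (v/v) trace declines linearly at ``rate_umol_per_day``
    (converted through the ideal gas law), floored at zero; Gaussian
    measurement noise of sd ``noise_sd`` (% v/v) is added and the reading
    clipped at zero.
    """
    if initial_pct < 0:
        raise ValueError("initial_pct must be >= 0")
    if rate_umol_per_day < 0:
        raise ValueError("rate must be >= 0")
    if headspace_ml <= 0:
        raise ValueError("headspace_ml must be > 0")
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(seed)
    # µmol of gas per % v/v of headspace (ideal gas)
    umol_per_pct = pressure_kPa * 1000.0 * (headspace_ml * 1e-8) / (8.314462618 * temperature_K) * 1e6
    pct_rate = rate_umol_per_day / umol_per_pct if umol_per_pct > 0 else 0.0
    expected = np.maximum(initial_pct - pct_rate * days, 0.0)
    observed = expected + (rng.normal(0.0, noise_sd, size=days.shape) if noise_sd > 0 else 0.0)
    return pd.DataFrame({"time_d": days, "pct_v_v": np.maximum(observed, 0.0)})


# ---------------------------------------------------------------------------
# Default study community
# ---------------------------------------------------------------------------

def default_community(
    n_taxa: int = 30,
    n_consumers: int = 3,
    atom_excess: float = 1.0,
    consumer_abundance: float = 0.06,
    substrates=("ethane", "propane"),
    seed=0,
) -> CommunityProfile:
    """Synthetic gas-seep community used throughout the test bench.

    Non-consumer GC is drawn on [0.50, 0.64] so unlabelled DNA bands in or
    just above the light window; consumer GC on [0.42, 0.52] so fully
    labelled consumer DNA bands inside the heavy window. Each consumer
    assimilates every design substrate and holds >= ``consumer_abundance``
    of the community; the remainder is a flat Dirichlet split.
    """
    rng = np.random.default_rng(seed)
    n_bg = n_taxa - n_consumers
    if n_bg < 0:
        raise ValueError("n_consumers exceeds n_taxa")
    bg_share = 1.0 - n_consumers * consumer_abundance
    if bg_share <= 0:
        raise ValueError("consumer abundances exceed the whole community")
    bg_ab = rng.dirichlet(np.full(n_bg, 1.0)) * bg_share if n_bg else np.array([])
    taxa = []
    for k in range(n_consumers):
        taxa.append(
            Taxon(
                id=f"consumer{k + 1}",
                gc=float(rng.uniform(0.42, 0.52)),
                rel_abundance=consumer_abundance,
                atom_excess=atom_excess,
                consumes=frozenset(substrates),
            )
        )
    for k in range(n_bg):
        taxa.append(
            Taxon(id=f"taxon{k + 1:02d}", gc=float(rng.uniform(0.50, 0.64)), rel_abundance=float(bg_ab[k]))
        )
    # wash tiny float drift so abundances sum to exactly 1
    total = sum(t.rel_abundance for t in taxa)
    taxa = [dataclasses.replace(t, rel_abundance=t.rel_abundance / total) for t in taxa]
    return CommunityProfile(taxa)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_fraction_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ground_truth(dataset: SIPDataset, path) -> None:
    cols = ["taxon", "substrate", "true_label"]
    truth = (
        dataset.truth[dataset.truth.isotope == "13C"][cols]
        .drop_duplicates()
        .sort_values(["substrate", "taxon"])
    )
    truth.to_csv(path, sep="\t", index=False)
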