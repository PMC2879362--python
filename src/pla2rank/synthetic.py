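"""Seeded synthetic-data generators for every pipeline input.

No structures, kinetic traces or plate data are deposited for this study, so
every stage is exercised on generated inputs whose statistical structure
matches the analyses: linear fluorimetric traces whose slopes follow a
logistic dose-response, cell plates with the stated per-medium fold
inductions (PGE2 23.3 / 18.3 / 2.8; nitrite 8.1 / 2.6 / 2.0 in DMEM, +0.1%
BSA, +2% FCS respectively), and toy protein-ligand complexes with analytic
pairwise energies.

A single seed fans out to independent per-generator streams via
numpy.random.SeedSequence, so modules are testable independently yet
reproducibly: identical config implies bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import CellAssayRecord, KineticTrace
from .solvation import born_energy
from .structures import Atom, Complex, Molecule, assign_parameters

__all__ = [
    "GeneratorConfig",
    "MEDIA",
    "make_toy_complex",
    "make_born_ion",
    "simulate_kinetics",
    "simulate_cell_plate",
]

MEDIA = ("DMEM", "DMEM+0.1%BSA", "DMEM+2%FCS")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Effect sizes are the stated per-medium fold inductions; noise defaults
    give replicate SEMs under ~10%, matching the reported assay precision.
    """

    seed: int = 0
    noise_cv: float = 0.10  # multiplicative noise, coefficient of variation
    kinetic_noise_sd: float = 0.5  # AU, additive on fluorescence
    replicates: int = 6  # per condition, within the reported 3-8 range
    pge2_folds: dict = field(default_factory=lambda: {
        "DMEM": 23.3, "DMEM+0.1%BSA": 18.3, "DMEM+2%FCS": 2.8,
    })
    nitrite_folds: dict = field(default_factory=lambda: {
        "DMEM": 8.1, "DMEM+0.1%BSA": 2.6, "DMEM+2%FCS": 2.0,
    })
    # C8 dose-response on the IL-1b-induced PGE2 increment (Emax model);
    # top doses bring secretion back to about the untreated level
    inhibition_emax: dict = field(default_factory=lambda: {
        "DMEM": 0.88, "DMEM+0.1%BSA": 1.0, "DMEM+2%FCS": 0.75,
    })
    inhibition_ec50_um: dict = field(default_factory=lambda: {
        "DMEM": 0.25, "DMEM+0.1%BSA": 1.3, "DMEM+2%FCS": 0.35,
    })
    c8_doses_um: dict = field(default_factory=lambda: {
        "DMEM": [0.31, 0.62, 0.94, 1.24],
        "DMEM+0.1%BSA": [0.31, 0.62, 0.94, 1.24, 2.48, 4.96],
        "DMEM+2%FCS": [0.31, 0.62, 0.94, 1.24, 2.48, 4.96],
    })
    baseline_pge2_pg_per_ug: float = 2.0
    baseline_nitrite_pmol_per_ug: float = 5.0
    protein_ug: float = 50.0

    def stream(self, label: str) -> np.random.Generator:
        """Independent, reproducible substream named by the consumer."""
        import zlib

        child = np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(label.encode()) % (2**31),)
        )
        return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _lattice_points(n: int, spacing: float, rng: np.random.Generator,
                    jitter: float) -> np.ndarray:
    """Jittered cubic-lattice positions, guaranteed non-overlapping."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.array(
        [[i, j, k] for i in range(side) for j in range(side) for k in range(side)]
    )[:n]
    return grid * spacing + rng.uniform(-jitter, jitter, size=(n, 3))


def make_toy_complex(seed: int = 0, n_protein_atoms: int = 20,
                     n_ligand_atoms: int = 8, ligand_net_charge: float = -1.0,
                     include_calcium: bool = True,
                     separation: float = 6.0) -> Complex:
    """Parameterized toy complex with non-overlapping geometry.

    The ligand is placed `separation` Angstrom from the protein face along x.
    The ligand carries the anionic net charge of the oxadiazolone chemotype
    by default (overridable); the Ca(II) cofactor is a +2 monatomic molecule
    between the partners.  All pairwise energies are analytic, so an O(n^2)
    oracle can check the interaction-energy routine.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    spacing, jitter = 3.5, 0.4

    prot_xyz = _lattice_points(n_protein_atoms, spacing, rng, jitter)
    prot_q = rng.uniform(-0.4, 0.4, n_protein_atoms)
    prot_q -= prot_q.mean()  # neutral protein fragment
    prot_elements = rng.choice(["C", "N", "O", "S"], size=n_protein_atoms,
                               p=[0.6, 0.18, 0.18, 0.04])
    protein = Molecule(
        atoms=[
            Atom(element=e, position=x, partial_charge=float(q), name=f"{e}{i+1}",
                 residue_id=i // 4 + 1)
            for i, (e, x, q) in enumerate(zip(prot_elements, prot_xyz, prot_q))
        ],
        name="toy-protein",
    )

    offset = np.array([prot_xyz[:, 0].max() + separation, 0.0, 0.0])
    lig_xyz = _lattice_points(n_ligand_atoms, spacing, rng, jitter) + offset
    lig_q = rng.uniform(-0.3, 0.3, n_ligand_atoms)
    lig_q += (ligand_net_charge - lig_q.sum()) / n_ligand_atoms
    lig_elements = rng.choice(["C", "N", "O"], size=n_ligand_atoms, p=[0.7, 0.15, 0.15])
    # chain topology so the ligand has bonded terms to strain
    lig_bonds = [(i, i + 1, 1) for i in range(n_ligand_atoms - 1)]
    ligand = Molecule(
        atoms=[
            Atom(element=e, position=x, partial_charge=float(q), name=f"{e}{i+1}")
            for i, (e, x, q) in enumerate(zip(lig_elements, lig_xyz, lig_q))
        ],
        bonds=lig_bonds,
        net_charge=float(lig_q.sum()),
        name="toy-ligand",
    )

    cofactors = []
    if include_calcium:
        ca_pos = 0.5 * (prot_xyz.mean(axis=0) + lig_xyz.mean(axis=0))
        ca_pos[1] += 2.0 * spacing  # keep clear of both partners
        cofactors.append(
            Molecule(
                atoms=[Atom(element="Ca", position=ca_pos, name="CA")],
                net_charge=2.0,
                name="calcium",
            )
        )

    protein = assign_parameters(protein)
    ligand = assign_parameters(ligand)
    cofactors = [assign_parameters(m) for m in cofactors]
    return Complex(protein=protein, ligand=ligand, cofactors=cofactors)


def make_born_ion(q: float = 1.0, radius: float = 2.0) -> Molecule:
    """Single-ion solute for PB validation; the closed-form Born energy
    (dielectric discontinuity at the bare radius) rides along as metadata."""
    mol = Molecule(
        atoms=[Atom(element="Na", position=(0.0, 0.0, 0.0), partial_charge=q,
                    radius=radius, name="ION")],
        net_charge=q,
        name=f"born-ion-q{q:g}-R{radius:g}",
    )
    mol.born_reference = {  # type: ignore[attr-defined]
        "eps_in_1_eps_out_80": born_energy(q, radius, 1.0, 80.0),
        "formula": "-166.03 * (1/eps_in - 1/eps_out) * q^2 / R",
    }
    return mol


# ---------------------------------------------------------------------------
# assays
# ---------------------------------------------------------------------------

def simulate_kinetics(config: GeneratorConfig, true_ic50: float,
                      concentrations, hill: float = 1.0,
                      control_slope: float = 12.0,
                      n_points: int = 13) -> list[KineticTrace]:
    """Fluorimetric traces whose initial rates follow a logistic inhibition
    curve around true_ic50.  Includes the uninhibited control (conc 0)."""
    rng = config.stream("kinetics")
    times = np.linspace(0.0, 60.0, n_points)
    traces = []
    for conc in [0.0, *list(concentrations)]:
        frac = 1.0 / (1.0 + (conc / true_ic50) ** hill) if conc > 0 else 1.0
        slope = control_slope * frac  # AU/min
        f = 5.0 + slope * times / 60.0
        if config.kinetic_noise_sd > 0:
            f = f + rng.normal(0.0, config.kinetic_noise_sd, size=times.shape)
        traces.append(
            KineticTrace(times=times, fluorescence=f, inhibitor_conc=float(conc))
        )
    return traces


def simulate_cell_plate(config: GeneratorConfig,
                        n_replicates: int | None = None) -> list[CellAssayRecord]:
    """Cell plate across the three media: untreated, IL-1b, IL-1b + C8 doses.

    PGE2 and nitrite per-protein means carry the configured fold inductions;
    C8 suppresses the IL-1b-induced PGE2 increment with an Emax dose-response
    (nitrite is left essentially uninhibited, as observed).  Multiplicative
    Gaussian noise with CV `noise_cv` on each replicate.
    """
    rng = config.stream("cells")
    n = n_replicates if n_replicates is not None else config.replicates
    records: list[CellAssayRecord] = []

    def noisy(mean: float) -> float:
        return float(mean * max(0.05, 1.0 + rng.normal(0.0, config.noise_cv)))

    for medium in MEDIA:
        pge2_base = config.baseline_pge2_pg_per_ug * config.protein_ug
        nit_base = config.baseline_nitrite_pmol_per_ug * config.protein_ug
        pge2_il = pge2_base * config.pge2_folds[medium]
        nit_il = nit_base * config.nitrite_folds[medium]
        conditions = [("untreated", 0.0, 0.0), ("IL1b", 1.0, 0.0)]
        conditions += [("IL1b+C8", 1.0, d) for d in config.c8_doses_um[medium]]
        for condition, il1b, dose in conditions:
            if condition == "untreated":
                pge2_mean, nit_mean, via = pge2_base, nit_base, 1.0
            elif condition == "IL1b":
                pge2_mean, nit_mean, via = pge2_il, nit_il, 1.1
            else:
                emax = config.inhibition_emax[medium]
                ec50 = config.inhibition_ec50_um[medium]
                inh = emax * dose / (dose + ec50)
                pge2_mean = pge2_base + (pge2_il - pge2_base) * (1.0 - inh)
                nit_mean, via = nit_il, 1.05
            for _ in range(n):
                a690 = 0.10
                a570 = a690 + 0.60 * noisy(via)
                records.append(
                    CellAssayRecord(
                        condition=condition,
                        medium=medium,
                        pge2=noisy(pge2_mean),
                        nitrite=noisy(nit_mean),
                        protein=noisy(config.protein_ug),
                        absorbance_570=a570,
                        absorbance_690=a690,
                        il1b_dose=il1b,
                        c8_dose=dose,
                    )
                )
    return records
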