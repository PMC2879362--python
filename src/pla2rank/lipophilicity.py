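"""Rekker fragmental log P calculation.

log P is estimated as the sum of group contributions, sum_n a_n * f_n, over
a fragment decomposition of the molecule, plus documented proximity /
conjugation corrections.  The fragmental-constant table ships as a versioned
CSV; the eight oxadiazolone compound definitions ship as curated fragment
lists (auditable line by line) rather than being perceived from SMILES.

Backbone fragments (CH2, C6H4, C6H5, aryl-ether O, aromatic Cl, ...) carry
revised-Rekker-style values; the oxadiazolone ring and the terminal aromatic
group constants are curated group values internally consistent across this
chemotype — no published fragmental constant exists for the
1,2,4-oxadiazol-5(4H)-one ring.  The neutral species is evaluated, following
the fragmental-method convention for ionizable solutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .structures import Molecule

__all__ = [
    "FragmentTable",
    "LipophilicityResult",
    "FragmentCoverageError",
    "load_fragment_table",
    "load_compound_fragments",
    "fragment_decompose",
    "rekker_logp",
    "compound_logp",
]


class FragmentCoverageError(ValueError):
    """A molecule (or fragment list) is not fully covered by the table."""


@dataclass(frozen=True)
class FragmentTable:
    entries: dict  # fragment key -> fragmental constant f
    corrections: dict  # correction key -> increment
    magic_constant: float
    version: str

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def f(self, key: str) -> float:
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"fragment key {key!r} not in table {self.version}") from None


@dataclass
class LipophilicityResult:
    log_p: float
    contributions: list  # (fragment key, count, count * f)
    corrections_applied: list  # (correction key, increment)

    def check(self, tol: float = 1e-9) -> None:
        total = sum(s for _, _, s in self.contributions) + sum(
            v for _, v in self.corrections_applied
        )
        assert abs(self.log_p - total) <= tol


def load_fragment_table() -> FragmentTable:
    data = resources.files("pla2rank.data")
    with data.joinpath("rekker_fragments.csv").open() as fh:
        df = pd.read_csv(fh)
    if df["key"].duplicated().any():
        raise ValueError("fragment table keys must be unique")
    with data.joinpath("compound_fragments.json").open() as fh:
        meta = json.load(fh)
    return FragmentTable(
        entries=dict(zip(df["key"], df["f"].astype(float))),
        corrections={k: float(v) for k, v in meta["corrections"].items()},
        magic_constant=float(meta["magic_constant"]),
        version=str(meta["version"]),
    )


def load_compound_fragments() -> dict:
    """Curated fragment decompositions of compounds C1-C8.

    Returns {compound: {"fragments": [(key, count), ...], "corrections": [...]}}.
    """
    with resources.files("pla2rank.data").joinpath("compound_fragments.json").open() as fh:
        meta = json.load(fh)
    return {
        name: {
            "name": spec.get("name", name),
            "fragments": [(k, int(c)) for k, c in spec["fragments"]],
            "corrections": list(spec["corrections"]),
        }
        for name, spec in meta["compounds"].items()
    }


# element counts per table fragment, used when decomposing a Molecule
_FRAGMENT_ATOMS = {
    "CH3": {"C": 1},
    "CH2": {"C": 1},
    "CH": {"C": 1},
    "C6H5": {"C": 6},
    "C6H4": {"C": 6},
    "C6H3": {"C": 6},
    "O_al": {"O": 1},
    "O_ar": {"O": 1},
    "OH_al": {"O": 1},
    "OH_ar": {"O": 1},
    "Cl_ar": {"Cl": 1},
    "Cl_al": {"Cl": 1},
}


def fragment_decompose(mol_or_fragments, table: FragmentTable | None = None):
    """Return a deterministic (fragment key, count) list.

    An explicit pre-fragmented list is passed through unchanged (after key
    validation).  For a Molecule, only simple hydrocarbon/ether patterns are
    perceived (heavy atoms greedily assigned to ring and chain fragments in
    atom order); anything uncovered raises FragmentCoverageError naming the
    atom.  The packaged compound definitions are curated lists, so Molecule
    perception is a convenience path for simple fixtures, not the audit path.
    """
    table = table or load_fragment_table()
    if not isinstance(mol_or_fragments, Molecule):
        frags = [(str(k), int(c)) for k, c in mol_or_fragments]
        unknown = [k for k, _ in frags if k not in table]
        if unknown:
            raise FragmentCoverageError(f"unknown fragment keys: {unknown}")
        return frags

    mol = mol_or_fragments
    heavy = [i for i, a in enumerate(mol.atoms) if a.element != "H"]
    adj = {i: set() for i in range(len(mol.atoms))}
    for i, j, _ in mol.bonds:
        adj[i].add(j)
        adj[j].add(i)

    assigned: dict[int, str] = {}
    counts: dict[str, int] = {}

    # 6-membered carbon rings -> phenyl/phenylene by substitution count
    import networkx as nx  # stdlib-adjacent; used only for cycle perception

    g = nx.Graph()
    g.add_nodes_from(heavy)
    g.add_edges_from(
        (i, j) for i, j, _ in mol.bonds if i in set(heavy) and j in set(heavy)
    )
    for ring in nx.cycle_basis(g):
        if len(ring) == 6 and all(mol.atoms[i].element == "C" for i in ring):
            subs = sum(
                1 for i in ring for nb in adj[i]
                if nb not in ring and mol.atoms[nb].element != "H"
            )
            key = {0: "C6H5", 1: "C6H5", 2: "C6H4", 3: "C6H3"}.get(subs)
            if key is None:
                raise FragmentCoverageError(
                    f"ring with {subs} substituents has no table fragment"
                )
            for i in ring:
                assigned[i] = key
            counts[key] = counts.get(key, 0) + 1

    for i in heavy:
        if i in assigned:
            continue
        a = mol.atoms[i]
        heavy_nb = [j for j in adj[i] if mol.atoms[j].element != "H"]
        n_h = sum(1 for j in adj[i] if mol.atoms[j].element == "H")
        aromatic_nb = any(assigned.get(j, "").startswith("C6") for j in heavy_nb)
        if a.element == "C":
            key = {3: "CH3", 2: "CH2", 1: "CH"}.get(n_h)
        elif a.element == "O":
            if n_h:
                key = "OH_ar" if aromatic_nb else "OH_al"
            else:
                key = "O_ar" if aromatic_nb else "O_al"
        elif a.element == "Cl":
            key = "Cl_ar" if aromatic_nb else "Cl_al"
        else:
            key = None
        if key is None or key not in table:
            near = ", ".join(sorted(table.entries)[:5])
            raise FragmentCoverageError(
                f"atom {i} ({a.element}) not covered; nearest candidates: {near}..."
            )
        assigned[i] = key
        counts[key] = counts.get(key, 0) + 1

    return sorted(counts.items())


def rekker_logp(fragments, table: FragmentTable | None = None,
                corrections: list[str] | None = None) -> LipophilicityResult:
    """Evaluate log P = sum a_n * f_n (+ named corrections) over a fragment list."""
    table = table or load_fragment_table()
    contribs = []
    total = 0.0
    for key, count in fragments:
        if key not in table:
            raise KeyError(f"fragment key {key!r} not in table {table.version}")
        sub = count * table.f(key)
        contribs.append((key, count, sub))
        total += sub
    applied = []
    for corr in corrections or []:
        try:
            inc = table.corrections[corr]
        except KeyError:
            raise KeyError(f"unknown correction {corr!r}") from None
        applied.append((corr, inc))
        total += inc
    result = LipophilicityResult(log_p=total, contributions=contribs,
                                 corrections_applied=applied)
    result.check()
    return result


def compound_logp(compound: str, table: FragmentTable | None = None) -> LipophilicityResult:
    """log P of one of the packaged compounds C1-C8 from its curated fragments."""
    table = table or load_fragment_table()
    defs = load_compound_fragments()
    if compound not in defs:
        raise KeyError(f"unknown compound {compound!r}; have {sorted(defs)}")
    spec = defs[compound]
    return rekker_logp(spec["fragments"], table, corrections=spec["corrections"])
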