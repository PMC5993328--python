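"""Structure-derived distances and per-substitution biophysical features.

Distances follow the convention used throughout the analysis: the distance of
a residue to the active site is the minimum over all active-site atoms to the
residue's C-alpha; the distance to the dimer interface is the minimum from
the residue's C-alpha to any atom of the partner chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "position", "wt", "mut", "ddG", "dist_active", "dist_interface",
    "depth", "conservation", "flexibility", "dlogP", "dSASA", "dpI",
]
POSITIONAL_FEATURES = ["dist_active", "dist_interface", "depth", "conservation", "flexibility"]


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, np.ndarray]  # atom name -> xyz (A)

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def coords(self) -> np.ndarray:
        return np.stack(list(self.atoms.values()))


@dataclass
class StructureModel:
    chains: dict[str, dict[int, Residue]]
    n_skipped: int = 0  # insertion-coded / non-standard residues dropped

    def chain(self, chain_id: str) -> dict[int, Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not in structure") from None


def parse_structure(path: str | Path) -> StructureModel:
    """Parse ATOM records of a PDB file into a light-weight model.

    HETATM records and waters are excluded; for disordered atoms the
    highest-occupancy conformer is kept; residues with insertion codes are
    skipped (counted).  Missing C-alpha atoms are logged, not fatal.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no ATOM records parsed from {path}") from None
    chains: dict[str, dict[int, Residue]] = {}
    n_skipped = 0
    for chain in model:
        residues: dict[int, Residue] = {}
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " ":
                continue  # HETATM / water
            if icode != " ":
                n_skipped += 1
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(),
                        key=lambda a: a.get_occupancy() or 0.0,
                    )
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if not atoms:
                continue
            if "CA" not in atoms:
                log.warning("residue %s%d has no C-alpha atom", chain.id, resseq)
            residues[resseq] = Residue(number=resseq, name=res.get_resname(), atoms=atoms)
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise ValueError(f"no ATOM records parsed from {path}")
    if n_skipped:
        log.info("skipped %d insertion-coded residues", n_skipped)
    return StructureModel(chains=chains, n_skipped=n_skipped)


def distance_to_active_site(
    model: StructureModel,
    target_residue: int,
    active_residue: int = 147,
    chain_id: str | None = None,
) -> float:
    """Min distance from any atom of the active residue to the target's C-alpha."""
    chain_id = chain_id or next(iter(model.chains))
    chain = model.chain(chain_id)
    if active_residue not in chain:
        raise ValueError(f"active-site residue {active_residue} absent from chain {chain_id!r}")
    if target_residue not in chain:
        raise ValueError(f"target residue {target_residue} absent from chain {chain_id!r}")
    target = chain[target_residue]
    if target.ca is None:
        raise ValueError(f"target residue {target_residue} has no C-alpha atom")
    active_coords = chain[active_residue].coords()
    return float(np.min(np.linalg.norm(active_coords - target.ca, axis=1)))


def distances_to_active_site(
    model: StructureModel, active_residue: int = 147, chain_id: str | None = None
) -> pd.Series:
    """Active-site distance for every residue of a chain that has a C-alpha."""
    chain_id = chain_id or next(iter(model.chains))
    chain = model.chain(chain_id)
    out = {
        num: distance_to_active_site(model, num, active_residue, chain_id)
        for num, res in sorted(chain.items())
        if res.ca is not None
    }
    return pd.Series(out, name="dist_active").rename_axis("position")


def distance_to_interface(
    model: StructureModel, chain_a: str, chain_b: str
) -> pd.Series:
    """Per residue of chain A: min distance from its C-alpha to any chain-B atom."""
    if len(model.chains) < 2:
        raise ValueError("interface distance requires >= 2 chains")
    a = model.chain(chain_a)
    b = model.chain(chain_b)
    b_coords = np.concatenate([res.coords() for res in b.values()])
    out = {}
    for num, res in sorted(a.items()):
        if res.ca is None:
            continue
        out[num] = float(np.min(np.linalg.norm(b_coords - res.ca, axis=1)))
    return pd.Series(out, name="dist_interface").rename_axis("position")


# ---------------------------------------------------------------------------
# amino-acid property deltas


def load_aa_properties() -> pd.DataFrame:
    """Bundled per-amino-acid physico-chemical property table (logP, pI)."""
    with resources.files("dmsenv.data").joinpath("aa_properties.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t").set_index("aa")


def property_deltas(
    wt_aa: str, mut_aa: str, properties: pd.DataFrame | None = None
) -> dict[str, float]:
    """Delta(property) = property(mut) - property(wt) for logP and pI."""
    props = properties if properties is not None else load_aa_properties()
    for aa in (wt_aa, mut_aa):
        if aa not in props.index:
            raise ValueError(f"nonstandard amino acid {aa!r}")
    return {
        "dlogP": float(props.loc[mut_aa, "logP"] - props.loc[wt_aa, "logP"]),
        "dpI": float(props.loc[mut_aa, "pI"] - props.loc[wt_aa, "pI"]),
    }


# ---------------------------------------------------------------------------
# feature-table ingestion


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table[[c for c in FEATURE_COLUMNS if c in table.columns]].to_csv(path, sep="\t", index=False)


def load_feature_table(
    path: str | Path,
    catalogue: pd.DataFrame | None = None,
    min_coverage: float = 0.9,
) -> pd.DataFrame:
    """Load a per-substitution feature TSV, optionally joined to a catalogue.

    Keys are (position, wt, mut) at amino-acid level.  Duplicate keys and
    positional features that differ between substitutions at one position are
    validation errors.  When a catalogue is given the join must cover at
    least ``min_coverage`` of its substitutions.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"position", "wt", "mut"} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing key columns: {sorted(missing)}")
    key = ["position", "wt", "mut"]
    if df.duplicated(key).any():
        dupes = df[df.duplicated(key, keep=False)][key].head()
        raise ValueError(f"duplicate substitution keys in feature table:\n{dupes}")
    for col in POSITIONAL_FEATURES:
        if col not in df.columns:
            continue
        per_pos = df.dropna(subset=[col]).groupby("position")[col].nunique()
        bad = per_pos[per_pos > 1]
        if not bad.empty:
            raise ValueError(
                f"positional feature {col!r} differs between substitutions at "
                f"positions {bad.index.tolist()}"
            )
    if catalogue is not None:
        cat = catalogue.rename(columns={"wt_aa": "wt", "mut_aa": "mut"})
        cat = cat[~cat["synonymous"].astype(bool)][key].drop_duplicates()
        merged = cat.merge(df, on=key, how="left")
        covered = merged[merged.columns.difference(key)].notna().any(axis=1)
        coverage = covered.mean() if len(merged) else 0.0
        if coverage < min_coverage:
            raise ValueError(
                f"feature table covers only {coverage:.1%} of library substitutions "
                f"(< {min_coverage:.0%})"
            )
        log.info("feature coverage: %.1f%%", 100 * coverage)
        return merged
    return df
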