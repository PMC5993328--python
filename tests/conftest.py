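import numpy as np
import pandas as pd
import pytest

from dmsenv import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        gene_length_codons=12,
        seed=7,
        depth_per_sample=5000,
        environments=(sim.EnvironmentSpec("reference"),),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Reference, catalogue, ground truth and counts for a 12-codon gene."""
    reference = sim.random_reference(small_config)
    catalogue = sim.generate_library(reference, small_config)
    truth = sim.ground_truth(sim.assign_true_features(catalogue, small_config), small_config)
    counts = sim.simulate_counts(truth, small_config)
    return {
        "config": small_config,
        "reference": reference,
        "catalogue": catalogue,
        "truth": truth,
        "counts": counts,
    }


def make_fitness_table(records, environment="env"):
    """FitnessTable from (position, wt, mut, synonymous, F_rep1, F_rep2) tuples.

    F values of None mean eliminated (no selected reads in that replicate).
    """
    rows = []
    for pos, wt, mut, syn, f1, f2 in records:
        reps = [f1, f2]
        numeric = [f for f in reps if f is not None]
        rows.append(
            {
                "position": pos,
                "wt": wt,
                "mut": mut,
                "synonymous": syn,
                "F_rep1": np.nan if f1 is None else f1,
                "F_rep2": np.nan if f2 is None else f2,
                "F": np.mean(numeric) if numeric else np.nan,
                "survived": bool(numeric),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["environment"] = environment
    return table


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, occupancy=1.0, altloc=" ",
                  element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          {element:>2}\n"
    )
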