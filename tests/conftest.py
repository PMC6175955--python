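import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hdxdiff as hd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SEED = 20180914


@pytest.fixture(scope="session")
def scenario_if():
    """Default toward_IF scenario used across modules."""
    return hd.default_transporter_scenario(300, "toward_IF", seed=SEED)


@pytest.fixture(scope="session")
def digest(scenario_if):
    return hd.digest_in_silico(
        scenario_if.sequence, target_coverage=0.8, seed=SEED, min_peptides=60
    )


@pytest.fixture(scope="session")
def simulated_pair(scenario_if, digest):
    """(control, variant) datasets with the default noise model."""
    cond = hd.LabelingConditions.detergent()
    noise = hd.NoiseModel(replicate_sd=0.05, seed=SEED)
    control = hd.simulate_dataset(
        scenario_if, digest.peptides, cond, "control", noise
    )
    variant = hd.simulate_dataset(
        scenario_if, digest.peptides, cond, "variant", noise
    )
    return control, variant


def write_pdb(path, residues, *, chain="A", multi=None):
    """Write a minimal fixed-width PDB.

    ``residues``: list of (resseq, resname, [(atom_name, element, xyz), ...]).
    ``multi``: optional list of coordinate arrays (one per MODEL), each of
    shape (n_atoms, 3) in the flattened atom order.
    """
    def atom_lines(coords_flat):
        lines = []
        serial = 0
        k = 0
        for resseq, resname, atoms in residues:
            for name, element, xyz in atoms:
                serial += 1
                x, y, z = (coords_flat[k] if coords_flat is not None else xyz)
                k += 1
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} "
                    f"{chain}{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}"
                )
        return lines

    out = []
    if multi is None:
        out.extend(atom_lines(None))
    else:
        for m, coords in enumerate(multi, start=1):
            out.append(f"MODEL     {m:4d}")
            out.extend(atom_lines(np.asarray(coords, dtype=float)))
            out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")
    return path
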