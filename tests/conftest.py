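import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def params():
    from redoxswitch import SchemeParams
    return SchemeParams()


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, element):
    return (f"ATOM  {serial:5d} {name:<4} {resname:>3} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n")


def make_pdb(models):
    """Build PDB text from [{(chain, resseq, resname): [(atom, element, xyz), ...]}]."""
    lines = []
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4}\n")
        serial = 1
        for (chain, resseq, resname), atoms in model.items():
            for (name, element, (x, y, z)) in atoms:
                lines.append(_pdb_atom(serial, name, resname, chain, resseq,
                                       x, y, z, element))
                serial += 1
        if multi:
            lines.append("ENDMDL\n")
    lines.append("END\n")
    return "".join(lines)


@pytest.fixture
def two_atom_pdb(tmp_path):
    text = make_pdb([{("A", 1, "GLY"): [("CA", "C", (0.0, 0.0, 0.0))],
                      ("A", 2, "GLY"): [("CA", "C", (3.0, 4.0, 0.0))]}])
    p = tmp_path / "two_atom.pdb"
    p.write_text(text)
    return p


@pytest.fixture
def multimodel_pdb(tmp_path):
    rng = np.random.default_rng(42)
    models = []
    for _ in range(3):
        jitter = rng.normal(0, 0.1, size=(2, 3))
        models.append({
            ("A", 1, "GLY"): [("CA", "C", tuple(jitter[0]))],
            ("A", 2, "GLY"): [("CA", "C", tuple(3.0 + jitter[1]))],
        })
    p = tmp_path / "multi.pdb"
    p.write_text(make_pdb(models))
    return p
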