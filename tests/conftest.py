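from __future__ import annotations

import numpy as np
import pytest


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


PDB_ATOM = (
    "ATOM  {serial:>5} {name:^4}{altloc}{resname:>3} {chain}{resseq:>4}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}           C\n"
)


def make_pdb(path, coords, bfactors=None, chain="A", resname="ALA", altlocs=None):
    """Write a minimal CA-only PDB file."""
    coords = np.asarray(coords, float)
    if bfactors is None:
        bfactors = [90.0] * len(coords)
    lines = []
    serial = 1
    for i, (xyz, b) in enumerate(zip(coords, bfactors), start=1):
        locs = altlocs.get(i, [" "]) if altlocs else [" "]
        for j, loc in enumerate(locs):
            x, y, z = xyz if j == 0 else xyz + 0.5
            lines.append(
                PDB_ATOM.format(
                    serial=serial, name="CA", altloc=loc, resname=resname,
                    chain=chain, resseq=i, x=x, y=y, z=z,
                    occ=1.0 if j == 0 else 0.5, bfac=b,
                )
            )
            serial += 1
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
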