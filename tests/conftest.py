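import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from trajcontacts import (
    GeometricCriteria, LigandSelection, run_worker, read_multimodel_pdb,
    assign_roles,
)
from trajcontacts.fixtures import (
    build_trajectory, build_frames, one_of_each_schedule, standard_schedule,
)


@pytest.fixture(scope="session")
def criteria():
    return GeometricCriteria()


@pytest.fixture(scope="session")
def lig_selection():
    return LigandSelection.parse("LIG")


@pytest.fixture(scope="session")
def tiny_traj(tmp_path_factory):
    """5-frame one-of-each trajectory on disk with its manifest."""
    d = tmp_path_factory.mktemp("tiny")
    path, manifest = build_trajectory(one_of_each_schedule(5), 5, d / "traj.pdb")
    return path, manifest


@pytest.fixture(scope="session")
def standard_traj(tmp_path_factory):
    """40-frame staggered 4-entry trajectory on disk with its manifest."""
    d = tmp_path_factory.mktemp("standard")
    path, manifest = build_trajectory(standard_schedule(40), 40, d / "traj.pdb")
    return path, manifest


@pytest.fixture(scope="session")
def standard_table(standard_traj, lig_selection):
    """Merged interaction table for the 40-frame standard trajectory."""
    path, manifest = standard_traj
    frames = read_multimodel_pdb(path)
    table = run_worker(frames, lig_selection, dt=10.0)
    return table, manifest
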