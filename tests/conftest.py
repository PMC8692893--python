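"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ignarkit import annotate, simulate
from ignarkit.seqio import SeqEntry


def germline_db_from(gl: simulate.SyntheticGermline) -> annotate.GermlineDB:
    d = {f"IGNARD{v.replace('IGNARV', '')}-{i + 1}": s
         for v, ds in gl.d.items() for i, s in enumerate(ds)}
    return annotate.GermlineDB(v=gl.v, j=gl.j, d=d,
                               v_anchor=gl.v_anchor, j_anchor=gl.j_anchor)


def references_from(gl: simulate.SyntheticGermline) -> list[SeqEntry]:
    from ignarkit.pipeline import _references_from_germline
    return _references_from_germline(gl)


def validation_preset(seed: int = 0) -> simulate.SimConfig:
    """Exact-recovery conditions: no noise, no trimming, unambiguous junctions."""
    cfg = simulate.SimConfig(seed=seed)
    r = cfg.repertoire
    r.shm_rate = 0.0
    r.seq_error = 0.0
    r.trim_mean = 0.0
    r.d_trim_mean = 0.0
    r.identifiable_junctions = True
    return cfg


@pytest.fixture(scope="session")
def sim_bundle():
    """One synthetic germline + database shared across annotation tests."""
    cfg = simulate.SimConfig(seed=7)
    rng = np.random.default_rng(7)
    gl = simulate.synthetic_germline(cfg.germline, rng)
    return cfg, gl, germline_db_from(gl)
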