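"""Shared fixtures.

The heavy end-to-end objects (a moderate-sedation synthetic cohort with its
graph metrics and PAC estimates) are session-scoped: the recovery and
drug-tracking tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import sedanet as sn
from sedanet.graphs import surrogate_normalize
from sedanet.spectral import BANDS


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_epochs() -> sn.EpochedData:
    """Deterministic 5-channel, 6-epoch noise segment at 250 Hz."""
    g = np.random.default_rng(99)
    data = g.standard_normal((6, 5, 2500))
    return sn.EpochedData(
        data=data, fs=250.0, labels=[f"E{i}" for i in range(5)]
    )


def _coupled_recording(seed: int = 0, n_epochs: int = 40) -> sn.Recording:
    """Six channels; only the (0, 1) pair shares a quarter-cycle-lag alpha
    source at high SNR."""
    g = np.zeros((6, 6))
    g[0, 1] = g[1, 0] = 1.0
    cfg = sn.SimulationConfig(
        n_channels=6, n_epochs=n_epochs, coupling_graph=g, snr=3.0, seed=seed
    )
    return sn.simulate_recording(cfg)


@pytest.fixture(scope="session")
def coupled_alpha() -> dict:
    """Alpha-band dwPLI of the single-pair coupled recording: per-pair band
    peak (`matrix`), peak frequencies, and in-band mean."""
    rec = _coupled_recording()
    ep = sn.baseline_correct(sn.epoch(sn.bandpass(rec)))
    tf = sn.tf_decompose(ep, fmax=20.0)
    conn = sn.dwpli(tf)
    matrix, peak = sn.band_connectivity(conn, (8.0, 15.0))
    mask = (conn.freqs >= 8) & (conn.freqs <= 15)
    return {
        "matrix": matrix,
        "peak_freq": peak,
        "band_mean": conn.dwpli[:, :, mask].mean(axis=-1),
    }


# ---------------------------------------------------------------------------
# session-scoped synthetic cohort at moderate sedation (recovery experiments)
# ---------------------------------------------------------------------------

RECOVERY_SEED = 7
RECOVERY_DENSITIES = np.array([0.1, 0.2, 0.3, 0.4, 0.5])


@pytest.fixture(scope="session")
def moderate_cohort():
    """10 + 10 participants, 32 channels, 20 x 10 s epochs, moderate level
    only (the level at which the group contrast is strongest)."""
    cfg = sn.CohortConfig(
        n_per_group={"responsive": 10, "drowsy": 10},
        base=sn.SimulationConfig(n_channels=32, n_epochs=20),
        seed=RECOVERY_SEED,
    )
    return sn.simulate_cohort(cfg, levels=("moderate",))


@pytest.fixture(scope="session")
def moderate_graph_metrics(moderate_cohort):
    """Surrogate-normalized graph metric summaries per participant.

    Time bins are coarsened to 0.08 s here (dwPLI averages over heavily
    overlapping frames, so halving the frame count leaves the estimate
    essentially unchanged while halving its cost)."""
    out = []
    for m in moderate_cohort:
        ep = sn.preprocess(m.recordings["moderate"])
        tf = sn.tf_decompose(ep, time_step=0.08, fmax=16.5)
        gm = surrogate_normalize(
            tf,
            BANDS["alpha"],
            densities=RECOVERY_DENSITIES,
            n_surrogates=10,
            louvain_reps=5,
            seed=101,
        )
        out.append((m, gm.summary()))
    return out


@pytest.fixture(scope="session")
def moderate_pac(moderate_cohort):
    """Occipital signed PAC per participant at moderate sedation."""
    rois = sn.default_rois(32)
    out = []
    for m in moderate_cohort:
        ep = sn.preprocess(m.recordings["moderate"])
        res = sn.pac_by_roi(ep, {"occipital": rois["occipital"]})
        out.append((m, res.roi_mean["occipital"]))
    return out
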