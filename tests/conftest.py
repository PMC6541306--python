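import warnings

import numpy as np
import pytest

from somvip.circuit import (
    AdaptationParams,
    CircuitSpec,
    ConnectivityParams,
    STFParams,
    build_circuit,
)


def motif_spec(w: float, b: float = 0.0, tau_a: float = 0.05, w_r: float = 0.0,
               variant: str = "som_vip_only", full_conn: bool = False,
               **kw) -> CircuitSpec:
    """Symmetric SOM-VIP motif (optionally embedded with PV) used across
    the regime and oscillation tests.

    ``full_conn`` makes the motif fully connected (within and between
    populations), matching the assumption behind the pathological
    winner-take-all boundaries; the mean-field quantities are
    connectivity-degree independent either way.
    """
    conn = ConnectivityParams().with_mutual_inhibition(w)
    if w_r:
        conn = conn.with_recurrence(w_r)
    if full_conn:
        prob = dict(conn.prob)
        for pair in (("S", "V"), ("V", "S"), ("S", "S"), ("V", "V")):
            prob[pair] = 1.0
        conn = replace_conn_prob(conn, prob)
    return CircuitSpec(
        connectivity=conn,
        adaptation=AdaptationParams.symmetric(b, tau_a),
        variant=variant,
        **kw,
    )


def replace_conn_prob(conn: ConnectivityParams, prob: dict) -> ConnectivityParams:
    from dataclasses import replace

    return replace(conn, prob=prob)


def build_quiet(spec, seed=0):
    """Build a circuit suppressing the intentional WTA-calibration warning
    (several tests deliberately probe the winner-take-all regime)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_circuit(spec, seed=seed)


@pytest.fixture
def fig1_spec() -> CircuitSpec:
    """Interneuron network of the baseline amplification configuration:
    mutual inhibition 0.7, adaptation b=0.2, STF U_s=0.4, tau_f=200 ms."""
    return CircuitSpec(
        connectivity=ConnectivityParams().with_mutual_inhibition(0.7),
        adaptation=AdaptationParams.symmetric(0.2, 0.1),
        stf=STFParams(u_s=0.4, tau_f=0.2),
        variant="interneuron_only",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
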