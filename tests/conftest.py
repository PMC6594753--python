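"""Shared fixtures: reference parameter sets and fast synthetic ensembles."""

import numpy as np
import pytest

from cftrpot import (
    DrugProtocol,
    GatingParams,
    Scheme,
    channel_site_concentration,
)

# Consensus wild-type parameter set of the two-site, one-compartment scheme
# (global-fit averages over three experimental patch pairs), with the
# standard channel-count convention: 100 channels in a 1e-16 L patch
# membrane.  k_in/k_out equals the octanol/water distribution coefficient
# 62580 within rounding of the published rates.
WT_TWO_SITE = dict(
    k_in=4034.0,
    k_out=0.06446,
    k_on=870.3,
    k_off=0.007451,
    po_ratio=3.935,
)


@pytest.fixture(scope="session")
def c_t_membrane() -> float:
    return channel_site_concentration(100, 1e-16)


@pytest.fixture(scope="session")
def wt_params(c_t_membrane) -> GatingParams:
    return GatingParams(c_t=c_t_membrane, **WT_TWO_SITE)


@pytest.fixture(scope="session")
def saturated_on_off() -> DrugProtocol:
    """1x-saturated (62 nM) application/washout, 10 min each."""
    return DrugProtocol.on_off(62e-9, 600.0, 600.0)


def fast_params(scheme: Scheme, c_t: float) -> GatingParams:
    """A parameter set with mild stiffness, for quick fitting tests."""
    kwargs = dict(k_in=6258.0, k_out=0.1, k_on=2e4, k_off=0.01,
                  po_ratio=4.0, c_t=c_t)
    if scheme.two_compartment:
        kwargs["k_flip"] = 0.05
    return GatingParams(**kwargs)
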