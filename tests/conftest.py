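import numpy as np
import pytest

from hetosc import ModelParameters, NeuronParameterTable, legendre_rule


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


def iapp_table(rule, Im, Is, params=None):
    """Network table with heterogeneous applied current Iapp = Im + Is*mu."""
    params = params or ModelParameters()
    return NeuronParameterTable.from_parameters(
        params, rule.weights, Iapp=Im + Is * rule.nodes
    )


def iapp_factory(rule, Is, params=None):
    """Im -> table factory for Hopf scans."""
    params = params or ModelParameters()

    def make(Im):
        return iapp_table(rule, Im, Is, params)

    return make


@pytest.fixture(scope="session")
def baseline_table(params):
    """The standard heterogeneous network: 10 Gauss-Legendre nodes,
    Iapp = 17.5 + 7.5*mu."""
    return iapp_table(legendre_rule(10), 17.5, 7.5, params)
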