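import numpy as np
import pytest

from b2mq.synthetic import (
    FiloSpec,
    NeuronSpec,
    TirfCellSpec,
    VcCellSpec,
    generate_neuron_image,
    generate_tirf_pair,
    simulate_vc,
)


@pytest.fixture(scope="session")
def tirf_pair_noiseless():
    """Noise-free two-channel cell with a 1.5x enriched border ring."""
    spec = TirfCellSpec(noise_sigma=0.0, enrichment_rho=1.5, seed=11)
    return generate_tirf_pair(spec), spec


@pytest.fixture(scope="session")
def tirf_pair_noisy():
    spec = TirfCellSpec(noise_sigma=0.10, enrichment_rho=1.34, seed=12)
    return generate_tirf_pair(spec), spec


@pytest.fixture(scope="session")
def cho_filopodia_pair():
    """Noise-free cell with five filopodia of known lengths, no lamellipodia."""
    spec = TirfCellSpec(
        noise_sigma=0.0, lamellipodia=(),
        filopodia=tuple(FiloSpec(a, l) for a, l in
                        ((20, 5.0), (100, 3.0), (170, 6.0), (250, 4.0), (320, 7.0))),
        seed=2)
    return generate_tirf_pair(spec), spec


@pytest.fixture(scope="session")
def neuron_default():
    spec = NeuronSpec(seed=3)
    return generate_neuron_image(spec), spec


@pytest.fixture(scope="session")
def vc_noisy_sweeps():
    spec = VcCellSpec(Gmax_nS=18.0, Ra_MOhm=9.0, Cm_pF=11.0, seed=21)
    return simulate_vc(spec), spec


@pytest.fixture(scope="session")
def vc_clean_sweeps():
    spec = VcCellSpec(Gmax_nS=20.0, Ra_MOhm=10.0, Cm_pF=10.0, noise_sigma=0.0, seed=22)
    return simulate_vc(spec), spec


@pytest.fixture(scope="session")
def circle_mask():
    mask = np.zeros((512, 512), dtype=bool)
    rr, cc = np.mgrid[0:512, 0:512]
    mask[np.hypot(rr - 256.0, cc - 256.0) <= 150.0] = True
    return mask
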