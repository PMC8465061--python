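import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: TTHA1359 dyad binding consensus: two 7-bp half sites around a 6-bp spacer.
CONSENSUS = "AWTGTRANNNNNNTYACAWT"

#: Determinate binding-parameter table rows: name -> (sequence, kon, koff, KD_nM).
BINDING_TABLE = {
    "wt": ("ATTGTGACACACATCACAAT", 457_555, 0.001577, 3.447),
    "wt_p3": ("ATgGTGACACACATCACAAT", 215_769, 0.01867, 86.53),
    "wt_p6": ("ATTGTtACACACATCACAAT", 288_341, 0.02153, 74.67),
    "wt_p7": ("ATTGTGgCACACATCACAAT", 267_033, 0.006236, 23.35),
    "CRP_Ec": ("AAATGTGATCTAGATCACATTT", 726_387, 0.0007341, 1.011),
}

#: Point mutants of the consensus probe (each one mismatch to the consensus).
POINT_MUTANTS = {
    "wt_p1": "cTTGTGACACACATCACAAT",
    "wt_p2": "AgTGTGACACACATCACAAT",
    "wt_p3": "ATgGTGACACACATCACAAT",
    "wt_p4": "ATTtTGACACACATCACAAT",
    "wt_p5": "ATTGgGACACACATCACAAT",
    "wt_p6": "ATTGTtACACACATCACAAT",
    "wt_p7": "ATTGTGgCACACATCACAAT",
}

#: Spacer-length mutants (5-bp and 7-bp spacers).
SPACER_MUTANTS = {"wt_s5": "ATTGTGAcacacTCACAAT", "wt_s7": "ATTGTGAcacacacTCACAAT"}

#: The five analyte concentrations (nM, dimeric protein) used for kinetics.
KINETIC_CONCS = [5.7, 17.0, 51.0, 153.0, 461.0]


def round_sig(x: float, sig: int = 4) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
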