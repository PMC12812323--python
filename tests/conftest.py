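import pytest

from gdmtopt import EligibilityRules, Formulary


@pytest.fixture(scope="session")
def formulary() -> Formulary:
    return Formulary.default()


@pytest.fixture(scope="session")
def rules() -> EligibilityRules:
    return EligibilityRules.default()


def make_snapshot(orders=(), *, sbp=120.0, pulse=75.0, potassium=4.2, egfr=65.0,
                  scr=1.1, nyha=2, intolerant=frozenset(), **kw):
    """A clinically unremarkable encounter (no eligibility rule fires)."""
    from gdmtopt import PatientSnapshot

    return PatientSnapshot(
        patient_id="test", orders=list(orders), sbp=sbp, pulse=pulse,
        potassium=potassium, egfr=egfr, scr=scr, nyha=nyha,
        intolerant_classes=frozenset(intolerant), **kw,
    )
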