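import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from seedscreen import data
from seedscreen.confirmation import SiRNAEvidence

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return data.load_table1()


@pytest.fixture(scope="session")
def table2():
    return data.load_table2()


@pytest.fixture(scope="session")
def table3():
    return data.load_table3()


def make_measurements(rows):
    """Rows of (plate, well, replicate, phase, fluorescence, role, sirna_id)."""
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "replicate", "phase", "fluorescence", "role", "sirna_id",
        ],
    )


@pytest.fixture
def toy_screen():
    """Two plates x 8 sample wells x 2 replicates, plus controls.

    Pre-treatment fluorescence values are distinct so the viability cut
    has no ties; survival varies per well.
    """
    rng = np.random.default_rng(42)
    rows = []
    lib_rows = []
    i = 0
    for plate in ("P1", "P2"):
        for w in range(8):
            sid = f"si{i:03d}"
            lib_rows.append((sid, f"G{i:03d}", "".join(rng.choice(list("ACGT"), 21))))
            i += 1
            for rep in (1, 2):
                pre = 1000.0 + 17 * i + 3 * rep + w
                surv = float(np.exp(rng.normal(-1.0, 0.5)))
                rows.append((plate, f"A{w + 1:02d}", rep, "pre", pre, "sample", sid))
                rows.append((plate, f"A{w + 1:02d}", rep, "post", pre * surv, "sample", sid))
        for rep in (1, 2):
            for w, role in ((9, "pos_ctrl"), (10, "neg_ctrl")):
                pre = 900.0 + w + rep
                surv = 0.9 if role == "pos_ctrl" else 0.2
                rows.append((plate, f"A{w + 1:02d}", rep, "pre", pre, role, None))
                rows.append((plate, f"A{w + 1:02d}", rep, "post", pre * surv, role, None))
    library = pd.DataFrame(lib_rows, columns=["sirna_id", "gene_id", "guide_seq"])
    return library, make_measurements(rows)


def evidence_for_status(gene: str, status: str) -> list[SiRNAEvidence]:
    """Synthetic confirmation evidence producing a given gene status.

    Encodes the four narrative patterns: on-target hits (two
    phenotype-positive siRNAs with the strongest knockdowns), off-target
    effects (a silent siRNA knocks down best), unconfirmed genes (only
    the screen siRNA reproduces, others are weaker on both axes), and
    false positives (the screen phenotype does not reproduce).
    """
    E = SiRNAEvidence
    if status == "Hit":
        return [
            E(f"{gene}_1", gene, True, 0.30, True, was_screen_sirna=True),
            E(f"{gene}_2", gene, True, 0.35, True),
            E(f"{gene}_3", gene, False, 0.80, True),
        ]
    if status == "OTE":
        return [
            E(f"{gene}_1", gene, True, 0.50, True, was_screen_sirna=True),
            E(f"{gene}_2", gene, True, 0.60, True),
            E(f"{gene}_3", gene, False, 0.30, True),
        ]
    if status == "Unconfirmed":
        return [
            E(f"{gene}_1", gene, True, 0.30, True, was_screen_sirna=True),
            E(f"{gene}_2", gene, False, 0.70, True),
            E(f"{gene}_3", gene, False, 0.80, True),
        ]
    if status == "False +ve":
        return [
            E(f"{gene}_1", gene, False, 0.40, True, was_screen_sirna=True),
            E(f"{gene}_2", gene, False, 0.60, True),
        ]
    raise ValueError(status)
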