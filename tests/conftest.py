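import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

#: The published 16-mer sparrow blocker in vendor notation, with the
#: spacing artifacts it is printed with.
BLOCKER_PRINTED = "/5AmMC6/C + AG + TY + GA + CC + TY + GC + AA+T/3AmMO/"
BLOCKER_CANONICAL = "/5AmMC6/C+AG+TY+GA+CC+TY+GC+AA+T/3AmMO/"

FORWARD_TAILED = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCTACAGGHTGRACHGTNTAYCC"
REVERSE_TAILED = "ACACTCTTTCCCTACACGACGCTCTTCCGATCTTCDGGRTGNCCRAARAAYCA"
FORWARD_TAIL_LEN = 34
REVERSE_TAIL_LEN = 33


@pytest.fixture
def blocker():
    from nestblock import parse_modified_oligo
    return parse_modified_oligo(BLOCKER_PRINTED)


@pytest.fixture
def primer_pair():
    from nestblock import PrimerPair, parse_modified_oligo
    return PrimerPair(parse_modified_oligo(FORWARD_TAILED),
                      parse_modified_oligo(REVERSE_TAILED),
                      FORWARD_TAIL_LEN, REVERSE_TAIL_LEN)


@pytest.fixture
def planted_fixture():
    """Default planted-window scenario: alignment + truth + id groups."""
    from nestblock.simulate import SimScenario, simulate_template_alignment
    sc = SimScenario()
    aln, truth = simulate_template_alignment(sc, seed=7)
    return sc, aln, truth


@pytest.fixture
def toy_table():
    """Small hand-countable paired read table.

    no_blocker: nest dominated by the builder; blocker: builder gone,
    rare taxa gain reads.
    """
    from nestblock import ReadTable
    rows = [
        ("n1", "no_blocker", "builder", 900),
        ("n1", "no_blocker", "moth", 5),
        ("n1", "no_blocker", "fly", 2),
        ("n1", "blocker", "builder", 1),
        ("n1", "blocker", "moth", 60),
        ("n1", "blocker", "fly", 25),
        ("n1", "blocker", "weasel", 3),
        ("n2", "no_blocker", "builder", 800),
        ("n2", "no_blocker", "moth", 10),
        ("n2", "blocker", "moth", 80),
        ("n2", "blocker", "snake", 1),
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "taxon_id", "count"])
    taxa = {
        "builder": {"group": "sparrow", "is_nest_builder_of": "brsp"},
        "moth": {"group": "insect", "is_nest_builder_of": None},
        "fly": {"group": "ectoparasite", "is_nest_builder_of": None},
        "weasel": {"group": "predator", "is_nest_builder_of": None},
        "snake": {"group": "predator", "is_nest_builder_of": None},
    }
    samples = {"n1": "brsp", "n2": "brsp"}
    return ReadTable(df, taxa, samples)
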