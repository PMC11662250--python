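"""Shared plumbing for the numbered analysis drivers.

The drivers run the reference emulated protocol on a 20,000-person synthetic
claims database (a quick desk-scale stand-in for the full 50,000-person
study conditions the test suite exercises).  The database is cached as CSV
under scratch/ so each driver can be run independently.
"""

from pathlib import Path

from ttemu import ClaimsDB, RunConfig, SimConfig, generate_population

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis_db"

ANALYSIS_N_PERSONS = 20_000
ANALYSIS_SEED = 7


def sim_config() -> SimConfig:
    return SimConfig(n_persons=ANALYSIS_N_PERSONS, seed=ANALYSIS_SEED)


def run_config(**overrides) -> RunConfig:
    return RunConfig.reference(seed=ANALYSIS_SEED, **overrides)


def get_db() -> ClaimsDB:
    if (SCRATCH / "persons.csv").exists():
        return ClaimsDB.read_csv(SCRATCH)
    db = generate_population(sim_config())
    SCRATCH.mkdir(parents=True, exist_ok=True)
    db.write_csv(SCRATCH)
    return db
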