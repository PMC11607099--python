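import pytest

from resusflow import clinical_content, runner_eval


@pytest.fixture(scope="session")
def content():
    return clinical_content.load_content()


@pytest.fixture(scope="session")
def perfect_records(content):
    """One completed perfect-run session per scenario (assist on)."""
    records = {}
    for scenario_id in ("A", "B"):
        policy = runner_eval.Policy.scripted(
            content.scenarios[scenario_id]["perfect_run"]
        )
        records[scenario_id] = runner_eval.run_session(
            content, scenario_id, policy, assist=True, seed=1
        )
    return records
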