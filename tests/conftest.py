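import numpy as np
import pytest

from crisiswarn import PersonalityProfile, load_default_lexicon


@pytest.fixture(scope="session")
def open_profile() -> PersonalityProfile:
    """High-openness/extraversion, zero-neuroticism reference personality."""
    return PersonalityProfile.from_sequence([0.8, 0.2, 0.6, 0.4, 0.0])


@pytest.fixture(scope="session")
def neurotic_profile() -> PersonalityProfile:
    """High-neuroticism reference personality."""
    return PersonalityProfile.from_sequence([0.0, 0.6, 0.1, 0.1, 0.9])


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


@pytest.fixture()
def lexicon_file(tmp_path):
    """Write a small lexicon TSV and return its path."""

    def _write(rows: list[str], header: bool = True):
        lines = []
        if header:
            lines.append(
                "event_id\tphrase\tweight\tstim_dis\tstim_ang\tstim_sur"
                "\tstim_fea\tstim_joy\tstim_sad"
            )
        lines.extend(rows)
        path = tmp_path / "lexicon.tsv"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
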