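import pytest

from oradex.lexicon import load_lexicons


@pytest.fixture(scope="session")
def bundle():
    return load_lexicons()


@pytest.fixture()
def course_note():
    """Factory: wrap body text in a minimal note with one course section."""
    from oradex.corpus_io import NoteRecord

    def make(body: str, note_id: str = "n1", subject_id: str = "s1"):
        return NoteRecord(
            note_id=note_id,
            subject_id=subject_id,
            hadm_id="h1",
            text="BRIEF HOSPITAL COURSE:\n" + body + "\n",
        )

    return make
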