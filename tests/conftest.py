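from datetime import datetime

import pytest

from sirvanlp.note_indexing import ClinicalNote, index_note
from sirvanlp.terminology import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def make_note(lexicon):
    """Index a snippet of note text with a fixed note date."""

    def _make(text, note_dt=datetime(2017, 3, 20, 10, 0), note_id="n1", patient_id="p1"):
        return index_note(
            ClinicalNote(note_id=note_id, patient_id=patient_id,
                         note_datetime=note_dt, text=text),
            lexicon,
        )

    return _make
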