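import datetime as dt

import pytest

from ontosig import datasets
from ontosig.tagging import Document, PeriodBinning


@pytest.fixture(scope="session")
def ontology():
    return datasets.fixture_ontology()


@pytest.fixture(scope="session")
def signal_table():
    return datasets.signal_table()


@pytest.fixture(scope="session")
def reference_labels():
    return datasets.reference_labels()


@pytest.fixture()
def study_binning():
    return PeriodBinning.yearly(dt.date(2011, 1, 1), dt.date(2015, 6, 30))


def make_doc(doc_id, tokens, day=dt.date(2012, 6, 1), channel="blog", group=None):
    return Document(doc_id=doc_id, channel=channel, timestamp=day,
                    group=group, tokens=tuple(tokens))


@pytest.fixture()
def make_document():
    return make_doc


def write_ontology_files(tmp_path, classes_rows, relations_rows=(), terms_rows=()):
    """Write minimal ontology CSVs into tmp_path and return their paths."""
    class_file = tmp_path / "classes.csv"
    lines = ["class_id,label,parent_ids,level"]
    lines += [",".join(r) for r in classes_rows]
    class_file.write_text("\n".join(lines) + "\n")

    relation_file = tmp_path / "relations.csv"
    lines = ["relation_name,domain_id,range_id"]
    lines += [",".join(r) for r in relations_rows]
    relation_file.write_text("\n".join(lines) + "\n")

    term_file = tmp_path / "terms.csv"
    lines = ["surface_form,concept_id,concept_kind"]
    lines += [",".join(r) for r in terms_rows]
    term_file.write_text("\n".join(lines) + "\n")
    return class_file, relation_file, term_file
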