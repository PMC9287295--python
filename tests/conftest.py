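import pytest

from statinscope.models import Hyperparameters
from statinscope.notes import default_dictionary
from statinscope.pipeline import extract_documents
from statinscope.synthetic_ehr import (
    SimConfig,
    TrueDisposition,
    default_disposition_mix,
    generate_bundle,
)
from statinscope.taxonomy import UseStatus


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def default_sim():
    """The default study-conditions cohort: n=2000, seed=7."""
    config = SimConfig(n_patients=2000, seed=7)
    bundles, truths = generate_bundle(config)
    return config, bundles, truths


@pytest.fixture(scope="session")
def nlp_data(default_sim, dictionary):
    """Mention documents + ground-truth labels for the default cohort's NLP
    dataset (stands in for the manually annotated sample)."""
    _, bundles, truths = default_sim
    docs, buckets, ascvd = extract_documents(bundles, dictionary)
    truth = {t.patient_id: t for t in truths}
    ids = sorted(docs)
    use_labels = {
        p: int(truth[p].true_use_status is UseStatus.USE_DOCUMENTED) for p in ids
    }
    reason_sets = {
        p: truth[p].true_reasons for p in ids
        if truth[p].true_use_status is UseStatus.NONUSE
    }
    return docs, use_labels, reason_sets


def nlp_only_mix():
    """Disposition mix concentrated on the NLP dataset (39/61 use/nonuse)."""
    mix = {d: 0.0 for d in TrueDisposition}
    mix[TrueDisposition.NLP_USE_DOCUMENTED] = 0.39
    mix[TrueDisposition.NLP_NONUSE] = 0.61
    return mix


@pytest.fixture(scope="session")
def reason_rich_data(dictionary):
    """A larger NLP-only cohort for reason-model tests (every patient has a
    mention document)."""
    config = SimConfig(n_patients=600, seed=13, disposition_mix=nlp_only_mix())
    bundles, truths = generate_bundle(config)
    docs, _, _ = extract_documents(bundles, dictionary)
    truth = {t.patient_id: t for t in truths}
    ids = sorted(docs)
    use_labels = {
        p: int(truth[p].true_use_status is UseStatus.USE_DOCUMENTED) for p in ids
    }
    reason_sets = {
        p: truth[p].true_reasons for p in ids
        if truth[p].true_use_status is UseStatus.NONUSE
    }
    return docs, use_labels, reason_sets


@pytest.fixture(scope="session")
def hp():
    return Hyperparameters(seed=13)
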