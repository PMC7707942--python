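import numpy as np
import pytest

from emrner.corpus import TagScheme, TaggedSentence, EntitySpan, spans_to_bio


@pytest.fixture(scope="session")
def scheme() -> TagScheme:
    return TagScheme()


@pytest.fixture(scope="session")
def fixture_conll() -> str:
    """Three hand-written sentences covering all four classes."""
    return (
        "头\tB-sym\n"
        "痛\tI-sym\n"
        "三\tO\n"
        "天\tO\n"
        "\n"
        "服\tO\n"
        "阿\tB-dru\n"
        "司\tI-dru\n"
        "匹\tI-dru\n"
        "林\tI-dru\n"
        "\n"
        "诊\tO\n"
        "断\tO\n"
        "肺\tB-dis\n"
        "炎\tI-dis\n"
        "行\tO\n"
        "胸\tB-ope\n"
        "片\tI-ope\n"
        "\n"
    )


@pytest.fixture(scope="session")
def fixture_sentences(fixture_conll):
    from emrner.corpus import read_conll
    return read_conll(fixture_conll)


def random_sentence(rng: np.random.Generator, scheme: TagScheme,
                    max_len: int = 30) -> TaggedSentence:
    """A random sentence with random non-overlapping entity spans."""
    n = int(rng.integers(1, max_len + 1))
    spans = random_spans(rng, scheme, n)
    tokens = tuple(chr(0x4E00 + int(c)) for c in rng.integers(0, 200, n))
    return TaggedSentence(tokens, tuple(spans_to_bio(n, spans)))


def random_spans(rng: np.random.Generator, scheme: TagScheme,
                 length: int) -> list[EntitySpan]:
    """A random legal (sorted, non-overlapping) span set over [0, length)."""
    spans = []
    pos = 0
    while pos < length:
        if rng.random() < 0.4:
            end = int(rng.integers(pos + 1, min(length, pos + 6) + 1))
            cls = str(rng.choice(scheme.classes))
            spans.append(EntitySpan(pos, end, cls))
            pos = end
        else:
            pos += int(rng.integers(1, 4))
    return spans
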