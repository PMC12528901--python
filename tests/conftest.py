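import pytest

from palmkit.synthetic_panel import build_panel


@pytest.fixture(scope="session")
def panel():
    """The default synthetic stand-in panel (deterministic, built once)."""
    return build_panel()


def brute_force_motifs(positives, negatives, min_len=2):
    """Independent oracle: enumerate every substring of the positives and
    filter by the presence/absence predicate."""
    candidates = set()
    for seq in positives:
        for i in range(len(seq)):
            for j in range(i + min_len, len(seq) + 1):
                candidates.add(seq[i:j])
    return {
        m
        for m in candidates
        if all(m in p for p in positives) and not any(m in n for n in negatives)
    }
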