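import numpy as np
import pytest

from gazefilt import (FixationModel, generate_fixation, table1_filters)


@pytest.fixture(scope="session")
def filters():
    """The reference SG/IIR/FIR triple at 1000 Hz."""
    return table1_filters(1000.0)


@pytest.fixture(scope="session")
def fixation_trace():
    """One default 30 s synthetic fixation trace (seed 0)."""
    return generate_fixation(FixationModel(seed=0))


@pytest.fixture(scope="session")
def fixation_blocks():
    """216 velocity-screened 256-sample blocks, per condition."""
    from gazefilt import apply_filter, find_clean_segments

    filts = table1_filters(1000.0)
    blocks = {name: [] for name in ("unfiltered", *filts)}
    seed = 0
    while len(blocks["unfiltered"]) < 216:
        trace = generate_fixation(FixationModel(seed=seed))
        seed += 1
        segset = find_clean_segments(trace)
        bounds = segset.block_bounds()
        filtered = {name: apply_filter(f, trace) for name, f in filts.items()}
        for a, b in bounds:
            if len(blocks["unfiltered"]) >= 216:
                break
            blocks["unfiltered"].append(trace.x[a:b])
            for name in filts:
                blocks[name].append(filtered[name].x[a:b])
    return blocks
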