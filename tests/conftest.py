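import pytest

from mitostruct import (ReadModel, default_config, simulate_cp_with_transfers,
                        simulate_genome, simulate_reads)


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic study: genome, truth, conformation-mixture long
    reads for the active repeat, and a chloroplast partner with planted
    transfers.  Shared across tests; nothing mutates it."""
    cfg = default_config(seed=11)
    cfg.read_model = ReadModel(n_reads=300, mean_length=6000, min_length=500)
    genome, truth = simulate_genome(cfg)
    active = truth.repeat_pairs[0]
    reads, read_truth = simulate_reads(
        genome, active, truth.recomb_freqs[active.repeat_id],
        cfg.read_model, seed=12)
    cp, cp_features, cp_truth = simulate_cp_with_transfers(
        genome, cfg.mtpt_plants, seed=13)
    return {"cfg": cfg, "genome": genome, "truth": truth, "active": active,
            "reads": reads, "read_truth": read_truth, "cp": cp,
            "cp_features": cp_features, "cp_truth": cp_truth}
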