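"""Independent simulation oracles used by the test suite.

These deliberately bypass the package's text rendering and closed-form
expressions: they draw the generative events directly and count unique
users by brute force, so they can vouch for both.
"""

import numpy as np

from adrsignal.synth import GenConfig


def monte_carlo_prr(
    config: GenConfig, drug: str, group: str, n_users: int, seed: int
) -> float:
    """Simulate the generative model and compute the PRR from exact
    unique-user counts (no text, no closed form)."""
    rng = np.random.default_rng(seed)
    drugs = config.drug_ids
    posts_per_user = rng.poisson(config.posts_per_user_mean, size=n_users)
    n_posts = int(posts_per_user.sum())
    owner = np.repeat(np.arange(n_users), posts_per_user)
    probs = np.array([config.drug_probs[d] for d in drugs])
    p = np.append(probs, 1.0 - probs.sum())
    drug_idx = rng.choice(len(drugs) + 1, size=n_posts, p=p / p.sum())

    all_groups = config.all_group_ids
    emit = np.array(
        [[config.emission.get(d, {}).get(g, 0.0) for g in all_groups] for d in drugs]
    )
    has_drug = drug_idx < len(drugs)
    emitted = np.zeros((n_posts, len(all_groups)), dtype=bool)
    emitted[has_drug] = (
        rng.random((int(has_drug.sum()), len(all_groups))) < emit[drug_idx[has_drug]]
    )
    any_adr = emitted.any(axis=1)
    g = all_groups.index(group)
    target = drugs.index(drug)
    is_target = has_drug & (drug_idx == target)
    is_other = has_drug & (drug_idx != target)
    n_d = len(np.unique(owner[is_target & any_adr]))
    n_dr = len(np.unique(owner[is_target & emitted[:, g]]))
    n_nd = len(np.unique(owner[is_other & any_adr]))
    n_ndr = len(np.unique(owner[is_other & emitted[:, g]]))
    return (n_dr / n_d) / (n_ndr / n_nd)
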