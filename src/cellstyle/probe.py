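"""Convolutional probe classifiers.

The mode-of-action / batch probe reuses the discriminator's trunk with a
softmax head and is trained on real labeled images with cross-entropy; at
evaluation it labels generated images so transformation quality can be read
as classification accuracy.
"""

from __future__ import annotations

import numpy as np

from . import ag
from .ag import Tensor
from .models import ModelConfig, _ConvTrunk
from .nn import Module
from .optim import Adam


class TrunkClassifier(Module):
    """Discriminator-architecture softmax classifier."""

    def __init__(self, cfg: ModelConfig, classes, seed=0):
        self.classes_ = np.asarray(classes)
        rng = np.random.default_rng(seed)
        self.trunk = _ConvTrunk(cfg, len(self.classes_), rng)

    def logits(self, images):
        return self.trunk(Tensor(np.asarray(images, dtype=np.float64)))

    def fit(self, images, labels, iterations=200, batch_size=16, lr=1e-3, seed=0):
        images = np.asarray(images, dtype=np.float64)
        class_index = {c: i for i, c in enumerate(self.classes_.tolist())}
        y = np.array([class_index[l] for l in np.asarray(labels).tolist()])
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=lr)
        for _ in range(iterations):
            idx = rng.choice(len(images), size=min(batch_size, len(images)), replace=False)
            logits = self.logits(images[idx])
            # cross entropy with log-sum-exp stabilization
            shift = Tensor(logits.data.max(axis=1, keepdims=True))
            z = ag.add(logits, ag.mul(shift, -1.0))
            logsumexp = ag.log(ag.tsum(ag.exp(z), axis=1, keepdims=True))
            logprob = ag.add(z, ag.mul(logsumexp, -1.0))
            picked = logprob[np.arange(len(idx)), y[idx]]
            loss = ag.mul(ag.tmean(picked), -1.0)
            opt.zero_grad()
            self.zero_grad()
            loss.backward()
            opt.step()
        return self

    def predict(self, images):
        with ag.no_grad():
            logits = self.logits(images)
        return self.classes_[np.argmax(logits.data, axis=1)]

    def score(self, images, labels):
        return float(np.mean(self.predict(images) == np.asarray(labels)))
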