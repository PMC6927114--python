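"""Character-based Bi-LSTM-CRF tagger over composed feature embeddings.

Each character is embedded by the feature model's composition layer, a
single-layer bidirectional LSTM produces contextual states, a linear
projection yields per-tag emission scores, and a linear-chain CRF with
virtual START/STOP states scores tag sequences.  Training minimises the
mean negative log-likelihood (log-partition minus gold-path score) with
Adam; the composition parameters LW/RW/b are updated jointly with the
network unless the model is the frozen Sum variant, and the pretrained
feature tables are fine-tuned by default.

Transition constraints: disallowed BIO transitions are pinned at a
large negative constant (−10⁴) during training, so the normaliser is
effectively restricted to valid paths while remaining finite; decoding
uses hard −∞ constraints, so the output is always BIO-valid.  Viterbi
ties break toward the lowest tag index for determinism.

All computation is dense numpy on CPU; gradients are derived manually
(standard LSTM backprop plus CRF forward–backward marginals).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from .corpus import TagSet, TaggedSentence, is_valid_bio
from .embeddings import CompositionParams, EmbeddingTable, FeatureModel

__all__ = ["TrainConfig", "CRFTagger", "sequence_score", "log_partition",
           "viterbi_decode", "train", "NEG_INF_TRANSITION"]

NEG_INF_TRANSITION = -1.0e4

logger = logging.getLogger(__name__)


def _chardb_hash(db) -> str:
    """Stable digest of the character table a model was trained against."""
    h = hashlib.sha256()
    for ch in sorted(db.records):
        rec = db.records[ch]
        readings = ";".join(p.raw for p in rec.readings)
        h.update(f"{ch}\t{rec.primary_radical}\t{readings}\t{rec.ids}\n"
                 .encode("utf-8"))
    return h.hexdigest()


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (all unit-free).

    Defaults are desk-scale: one Bi-LSTM layer of 100 hidden units per
    direction, Adam at 1e-3, 20 epochs, batches of 32.
    """

    hidden: int = 100
    lr: float = 2e-3
    epochs: int = 20
    batch_size: int = 32
    seed: int = 13
    fine_tune_embeddings: bool = True
    clip: float = 5.0
    shuffle: bool = True


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _logsumexp(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


class CRFTagger:
    """Bi-LSTM emission scorer plus linear-chain CRF transitions."""

    def __init__(self, feature_model: FeatureModel, tagset: TagSet | None = None,
                 hidden: int = 100, seed: int = 0):
        self.feature_model = feature_model
        self.tagset = tagset or TagSet()
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        D = feature_model.params.out_dim
        H = hidden
        K = self.tagset.n_tags

        def glorot(shape):
            scale = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-scale, scale, size=shape)

        self.params: dict[str, np.ndarray] = {}
        for d in ("f", "b"):  # forward / backward direction
            self.params[f"Wx_{d}"] = glorot((4 * H, D))
            self.params[f"Wh_{d}"] = glorot((4 * H, H))
            bias = np.zeros(4 * H)
            bias[H:2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = bias
        self.params["W_out"] = glorot((K, 2 * H))
        self.params["b_out"] = np.zeros(K)
        trans = rng.standard_normal((K + 2, K + 2)) * 0.01
        trans[~self.tagset.allowed] = NEG_INF_TRANSITION
        trans[:, self.tagset.start] = NEG_INF_TRANSITION
        trans[self.tagset.stop, :] = NEG_INF_TRANSITION
        self.params["trans"] = trans

        # trainable embedding matrices, one row per token plus UNK row
        self._left_tokens = list(feature_model.left_table.vectors)
        self._right_tokens = list(feature_model.right_table.vectors)
        self._left_index = {t: i for i, t in enumerate(self._left_tokens)}
        self._right_index = {t: i for i, t in enumerate(self._right_tokens)}
        lt, rt = feature_model.left_table, feature_model.right_table
        self.params["E_left"] = np.vstack(
            [np.stack([lt.vectors[t] for t in self._left_tokens])
             if self._left_tokens else np.zeros((0, lt.dim)),
             lt.unk_vector[None, :]]).astype(np.float64)
        self.params["E_right"] = np.vstack(
            [np.stack([rt.vectors[t] for t in self._right_tokens])
             if self._right_tokens else np.zeros((0, rt.dim)),
             rt.unk_vector[None, :]]).astype(np.float64)

    # ---------- feature indexing ----------

    def _token_rows(self, chars) -> tuple[np.ndarray, np.ndarray]:
        left_unk = len(self._left_tokens)
        right_unk = len(self._right_tokens)
        li, ri = [], []
        for ch in chars:
            lt, rt = self.feature_model.feature_tokens(ch)
            li.append(self._left_index.get(lt, left_unk) if lt else left_unk)
            ri.append(self._right_index.get(rt, right_unk) if rt else right_unk)
        return np.array(li), np.array(ri)

    # ---------- forward network ----------

    def _emissions_batch(self, batch: list, want_cache: bool = False):
        """Emission scores for a batch of char sequences.

        Returns (emissions (B,T,K), mask (B,T), cache-for-backprop).
        """
        B = len(batch)
        lengths = np.array([len(s) for s in batch])
        T = int(lengths.max())
        H = self.hidden
        K = self.tagset.n_tags
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(np.float64)

        left_idx = np.zeros((B, T), dtype=int)
        right_idx = np.zeros((B, T), dtype=int)
        for b, chars in enumerate(batch):
            li, ri = self._token_rows(chars)
            left_idx[b, :len(chars)] = li
            right_idx[b, :len(chars)] = ri
            left_idx[b, len(chars):] = len(self._left_tokens)
            right_idx[b, len(chars):] = len(self._right_tokens)

        EL = self.params["E_left"][left_idx]     # (B,T,dl)
        ER = self.params["E_right"][right_idx]   # (B,T,dr)
        cp = self.feature_model.params
        E = EL @ cp.LW.T + ER @ cp.RW.T + cp.b   # (B,T,D)

        caches = {}
        hs = {}
        for d, order in (("f", range(T)), ("b", range(T - 1, -1, -1))):
            Wx, Wh, bias = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"],
                            self.params[f"b_{d}"])
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            steps = []
            out = np.zeros((B, T, H))
            for t in order:
                x = E[:, t]
                z = x @ Wx.T + h @ Wh.T + bias
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                m = mask[:, t][:, None]
                c_new = (f * c + i * g) * m
                tanh_c = np.tanh(c_new)
                h_new = (o * tanh_c) * m
                steps.append(dict(t=t, x=x, h_prev=h, c_prev=c, i=i, f=f,
                                  g=g, o=o, c=c_new, tanh_c=tanh_c, m=m))
                h, c = h_new, c_new
                out[:, t] = h
            caches[d] = steps
            hs[d] = out

        Hcat = np.concatenate([hs["f"], hs["b"]], axis=2)  # (B,T,2H)
        emis = Hcat @ self.params["W_out"].T + self.params["b_out"]
        emis = emis * mask[:, :, None]
        if want_cache:
            cache = dict(EL=EL, ER=ER, left_idx=left_idx, right_idx=right_idx,
                         E=E, caches=caches, Hcat=Hcat, mask=mask)
            return emis, mask, cache
        return emis, mask, None

    def _backprop_emissions(self, d_emis, cache, grads):
        """Accumulate gradients of sum(d_emis * emissions) into *grads*."""
        H = self.hidden
        mask = cache["mask"]
        d_emis = d_emis * mask[:, :, None]
        Hcat = cache["Hcat"]
        B, T, _ = Hcat.shape
        grads["W_out"] += np.einsum("btk,bth->kh", d_emis, Hcat)
        grads["b_out"] += d_emis.sum(axis=(0, 1))
        dHcat = d_emis @ self.params["W_out"]  # (B,T,2H)
        dE = np.zeros_like(cache["E"])

        for d, sl in (("f", slice(0, H)), ("b", slice(H, 2 * H))):
            Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(self.params[f"b_{d}"])
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for step in reversed(cache["caches"][d]):
                t = step["t"]
                m = step["m"]
                dh = dHcat[:, t, sl] + dh_next
                # h = (o * tanh(c)) * m ; c = (f*c_prev + i*g) * m
                do = dh * step["tanh_c"] * m
                dc = dh * step["o"] * (1 - step["tanh_c"] ** 2) * m + dc_next
                di = dc * step["g"] * m
                df = dc * step["c_prev"] * m
                dg = dc * step["i"] * m
                dc_prev = dc * step["f"] * m
                dz = np.concatenate([
                    di * step["i"] * (1 - step["i"]),
                    df * step["f"] * (1 - step["f"]),
                    dg * (1 - step["g"] ** 2),
                    do * step["o"] * (1 - step["o"]),
                ], axis=1)
                dWx += dz.T @ step["x"]
                dWh += dz.T @ step["h_prev"]
                db += dz.sum(axis=0)
                dE[:, t] += dz @ Wx
                dh_next = dz @ Wh
                dc_next = dc_prev
            grads[f"Wx_{d}"] += dWx
            grads[f"Wh_{d}"] += dWh
            grads[f"b_{d}"] += db

        # through the composition layer
        cp = self.feature_model.params
        dE = dE * mask[:, :, None]
        if cp.trainable:
            grads["LW"] += np.einsum("btd,bte->de", dE, cache["EL"])
            grads["RW"] += np.einsum("btd,bte->de", dE, cache["ER"])
            grads["cb"] += dE.sum(axis=(0, 1))
        dEL = dE @ cp.LW  # (B,T,dl)
        dER = dE @ cp.RW
        np.add.at(grads["E_left"], cache["left_idx"].ravel(),
                  dEL.reshape(-1, dEL.shape[-1]))
        np.add.at(grads["E_right"], cache["right_idx"].ravel(),
                  dER.reshape(-1, dER.shape[-1]))

    # ---------- CRF ----------

    def _crf_forward(self, emis, mask):
        """Batched forward recursion; returns (alphas (B,T,K), logZ (B,))."""
        ts = self.tagset
        K = ts.n_tags
        trans = self.params["trans"]
        B, T, _ = emis.shape
        alphas = np.zeros((B, T, K))
        alpha = trans[ts.start, :K][None, :] + emis[:, 0]
        alphas[:, 0] = alpha
        for t in range(1, T):
            new = _logsumexp(alpha[:, :, None] + trans[None, :K, :K], axis=1)
            new = new + emis[:, t]
            m = mask[:, t][:, None]
            alpha = m * new + (1 - m) * alpha
            alphas[:, t] = alpha
        logZ = _logsumexp(alpha + trans[:K, ts.stop][None, :], axis=1)
        return alphas, logZ

    def _crf_backward(self, emis, mask):
        """Batched backward recursion; betas (B,T,K)."""
        ts = self.tagset
        K = ts.n_tags
        trans = self.params["trans"]
        B, T, _ = emis.shape
        betas = np.zeros((B, T, K))
        beta = np.broadcast_to(trans[:K, ts.stop], (B, K)).copy()
        betas[:, T - 1] = beta
        for t in range(T - 2, -1, -1):
            inner = trans[None, :K, :K] + (emis[:, t + 1] + beta)[:, None, :]
            new = _logsumexp(inner, axis=2)
            m = mask[:, t + 1][:, None]
            beta = m * new + (1 - m) * beta
            betas[:, t] = beta
        return betas

    def _gold_scores(self, emis, mask, tag_ids):
        """Batched gold-path scores (emissions + transitions incl. START/STOP)."""
        ts = self.tagset
        trans = self.params["trans"]
        B, T, _ = emis.shape
        lengths = mask.sum(axis=1).astype(int)
        scores = np.zeros(B)
        for b in range(B):
            L = lengths[b]
            ids = tag_ids[b][:L]
            scores[b] = emis[b, np.arange(L), ids].sum()
            path = np.concatenate(([ts.start], ids, [ts.stop]))
            scores[b] += trans[path[:-1], path[1:]].sum()
        return scores

    # ---------- public scoring ops ----------

    def sequence_score(self, sentence, tags) -> float:
        """CRF score of one (sentence, tag path): emissions plus
        transitions including START→first and last→STOP."""
        if len(sentence) != len(tags):
            raise ValueError("sentence / tag length mismatch")
        emis, mask, _ = self._emissions_batch([list(sentence)])
        ids = np.array([[self.tagset.index(t) for t in tags]])
        return float(self._gold_scores(emis, mask, ids)[0])

    def log_partition(self, sentence) -> float:
        """log Σ_paths exp(score); forward recursion in log space."""
        emis, mask, _ = self._emissions_batch([list(sentence)])
        _, logZ = self._crf_forward(emis, mask)
        return float(logZ[0])

    def neg_log_likelihood(self, sentence, tags) -> float:
        return self.log_partition(sentence) - self.sequence_score(sentence, tags)

    def viterbi_decode(self, sentence) -> TaggedSentence:
        """Highest-scoring BIO-valid tag path (hard constraints, ties to
        the lowest tag index)."""
        chars = list(sentence)
        if not chars:
            raise ValueError("empty sentence")
        ts = self.tagset
        K = ts.n_tags
        emis, mask, _ = self._emissions_batch([chars])
        emis = emis[0]
        T = len(chars)
        trans = np.where(ts.allowed, self.params["trans"], -np.inf)
        delta = trans[ts.start, :K] + emis[0]
        back = np.zeros((T, K), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + trans[:K, :K]
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(K)] + emis[t]
        final = delta + trans[:K, ts.stop]
        best = int(np.argmax(final))
        path = [best]
        for t in range(T - 1, 0, -1):
            best = int(back[t, best])
            path.append(best)
        path.reverse()
        return TaggedSentence(tuple(chars), tuple(ts.tags[i] for i in path))

    # ---------- training ----------

    def _trainable_names(self, config: TrainConfig) -> list[str]:
        names = [n for n in self.params if n != "trans"] + ["trans"]
        if not config.fine_tune_embeddings:
            names = [n for n in names if n not in ("E_left", "E_right")]
        return names

    def _loss_and_grads(self, batch_chars, batch_tagids, grads):
        emis, mask, cache = self._emissions_batch(batch_chars, want_cache=True)
        ts = self.tagset
        K = ts.n_tags
        B, T, _ = emis.shape
        alphas, logZ = self._crf_forward(emis, mask)
        betas = self._crf_backward(emis, mask)
        gold = self._gold_scores(emis, mask, batch_tagids)
        nll = (logZ - gold)

        lengths = mask.sum(axis=1).astype(int)
        # unary marginals
        logp = alphas + betas - logZ[:, None, None]
        marg = np.exp(logp) * mask[:, :, None]
        d_emis = marg.copy()
        for b in range(B):
            d_emis[b, np.arange(lengths[b]), batch_tagids[b][:lengths[b]]] -= 1.0

        trans = self.params["trans"]
        d_trans = grads["trans"]
        # pairwise expected transition counts minus gold counts
        for t in range(1, T):
            act = mask[:, t] > 0
            if not act.any():
                break
            lp = (alphas[act, t - 1][:, :, None] + trans[None, :K, :K]
                  + (emis[act, t] + betas[act, t])[:, None, :]
                  - logZ[act][:, None, None])
            d_trans[:K, :K] += np.exp(lp).sum(axis=0)
        # START / STOP rows
        p0 = np.exp(alphas[:, 0] + betas[:, 0] - logZ[:, None])
        d_trans[ts.start, :K] += p0.sum(axis=0)
        last = lengths - 1
        p_last = np.exp(alphas[np.arange(B), last] + trans[:K, ts.stop][None, :]
                        - logZ[:, None])
        d_trans[:K, ts.stop] += p_last.sum(axis=0)
        for b in range(B):
            ids = batch_tagids[b][:lengths[b]]
            path = np.concatenate(([ts.start], ids, [ts.stop]))
            np.add.at(d_trans, (path[:-1], path[1:]), -1.0)

        self._backprop_emissions(d_emis, cache, grads)
        return float(nll.sum())

    def train(self, corpus: list[TaggedSentence], config: TrainConfig | None = None):
        """Minimise mean NLL over *corpus*; returns the per-epoch loss trace.

        Raises before training if any sentence's tag sequence violates
        the BIO constraints.
        """
        config = config or TrainConfig(hidden=self.hidden)
        if not corpus:
            raise ValueError("empty training corpus")
        for k, sent in enumerate(corpus):
            if not is_valid_bio(sent.tags, self.tagset):
                raise ValueError(f"sentence {k} has an invalid BIO tag sequence")
        rng = np.random.default_rng(config.seed)
        cp = self.feature_model.params
        comp_trainable = cp.trainable
        names = self._trainable_names(config)
        comp_names = ["LW", "RW", "cb"] if comp_trainable else []

        # Adam state
        mstate = {n: np.zeros_like(self.params[n]) for n in names}
        vstate = {n: np.zeros_like(self.params[n]) for n in names}
        comp_params = {"LW": cp.LW, "RW": cp.RW, "cb": cp.b}
        for n in comp_names:
            mstate[n] = np.zeros_like(comp_params[n])
            vstate[n] = np.zeros_like(comp_params[n])
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        tag_ids = [np.array([self.tagset.index(t) for t in s.tags])
                   for s in corpus]
        order = np.arange(len(corpus))
        trace = []
        for epoch in range(config.epochs):
            if config.shuffle:
                rng.shuffle(order)
            total = 0.0
            for lo in range(0, len(corpus), config.batch_size):
                idx = order[lo:lo + config.batch_size]
                batch = [list(corpus[i].chars) for i in idx]
                bt = [tag_ids[i] for i in idx]
                grads = {n: np.zeros_like(self.params[n]) for n in names}
                for n in comp_names:
                    grads[n] = np.zeros_like(comp_params[n])
                if "E_left" not in grads:
                    grads["E_left"] = np.zeros_like(self.params["E_left"])
                    grads["E_right"] = np.zeros_like(self.params["E_right"])
                if not comp_trainable:
                    grads.setdefault("LW", np.zeros_like(cp.LW))
                    grads.setdefault("RW", np.zeros_like(cp.RW))
                    grads.setdefault("cb", np.zeros_like(cp.b))
                total += self._loss_and_grads(batch, bt, grads)
                step += 1
                scale = 1.0 / len(idx)
                for n in names + comp_names:
                    g = grads[n] * scale
                    if config.clip:
                        norm = np.linalg.norm(g)
                        if norm > config.clip:
                            g = g * (config.clip / norm)
                    mstate[n] = beta1 * mstate[n] + (1 - beta1) * g
                    vstate[n] = beta2 * vstate[n] + (1 - beta2) * g * g
                    mhat = mstate[n] / (1 - beta1 ** step)
                    vhat = vstate[n] / (1 - beta2 ** step)
                    upd = config.lr * mhat / (np.sqrt(vhat) + eps)
                    if n in comp_names:
                        comp_params[n] -= upd
                    else:
                        self.params[n] -= upd
                # keep disallowed transitions pinned
                tr = self.params["trans"]
                tr[~self.tagset.allowed] = NEG_INF_TRANSITION
                tr[:, self.tagset.start] = NEG_INF_TRANSITION
                tr[self.tagset.stop, :] = NEG_INF_TRANSITION
            trace.append(total / len(corpus))
        self._sync_tables()
        return trace

    def _sync_tables(self) -> None:
        """Write fine-tuned embedding rows back into the feature tables."""
        fm = self.feature_model
        for tok, i in self._left_index.items():
            fm.left_table.vectors[tok] = self.params["E_left"][i].astype(np.float32)
        fm.left_table.unk_vector = self.params["E_left"][-1].astype(np.float32)
        for tok, i in self._right_index.items():
            fm.right_table.vectors[tok] = self.params["E_right"][i].astype(np.float32)
        fm.right_table.unk_vector = self.params["E_right"][-1].astype(np.float32)

    # ---------- persistence ----------

    def save(self, path) -> None:
        """Single-archive checkpoint: config, vocabularies, tensors."""
        cp = self.feature_model.params
        meta = dict(mode=self.feature_model.mode, hidden=self.hidden,
                    types=list(self.tagset.types),
                    trainable=cp.trainable,
                    left_tokens=self._left_tokens,
                    right_tokens=self._right_tokens,
                    chardb_hash=_chardb_hash(self.feature_model.db))
        arrays = {f"p_{k}": v for k, v in self.params.items()}
        arrays.update(c_LW=cp.LW, c_RW=cp.RW, c_b=cp.b)
        with open(path, "wb") as fh:  # exact path, no .npz suffix magic
            np.savez_compressed(fh, meta=json.dumps(meta, ensure_ascii=False),
                                **arrays)

    @classmethod
    def load(cls, path, db) -> "CRFTagger":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = {k[2:]: z[k] for k in z.files if k.startswith("p_")}
            c_LW, c_RW, c_b = z["c_LW"], z["c_RW"], z["c_b"]
        stored = meta.get("chardb_hash")
        if stored and stored != _chardb_hash(db):
            logger.warning("character table differs from the one this model "
                           "was trained with; decoding may be inconsistent")
        dim_l = arrays["E_left"].shape[1]
        dim_r = arrays["E_right"].shape[1]
        left = EmbeddingTable(dim=dim_l, vectors={
            t: arrays["E_left"][i].astype(np.float32)
            for i, t in enumerate(meta["left_tokens"])},
            unk_vector=arrays["E_left"][-1].astype(np.float32))
        right = EmbeddingTable(dim=dim_r, vectors={
            t: arrays["E_right"][i].astype(np.float32)
            for i, t in enumerate(meta["right_tokens"])},
            unk_vector=arrays["E_right"][-1].astype(np.float32))
        params = CompositionParams(LW=c_LW, RW=c_RW, b=c_b,
                                   trainable=bool(meta["trainable"]))
        fm = FeatureModel(mode=meta["mode"], left_table=left,
                          right_table=right, params=params, db=db)
        tagger = cls(fm, TagSet(types=tuple(meta["types"])),
                     hidden=int(meta["hidden"]))
        for k, v in arrays.items():
            tagger.params[k] = v.astype(np.float64)
        return tagger


# ---------- functional wrappers (module-level API) ----------

def sequence_score(tagger: CRFTagger, sentence, tags) -> float:
    return tagger.sequence_score(sentence, tags)


def log_partition(tagger: CRFTagger, sentence) -> float:
    return tagger.log_partition(sentence)


def viterbi_decode(tagger: CRFTagger, sentence) -> TaggedSentence:
    return tagger.viterbi_decode(sentence)


def train(tagger: CRFTagger, corpus, config: TrainConfig | None = None):
    return tagger.train(corpus, config)
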