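"""The four scaffold-conditioned generator architectures.

All four are encoder-decoder models taking a scaffold (one or more
fragments) as input and emitting a complete molecule:

* ``GraphTransformerGenerator`` -- transformer over five-row graph-matrix
  columns; each decoding step predicts atom type, bond type, connected
  index and current index sequentially through a GRU cell, and sampling
  applies the valence mask at every step so every emission decodes to a
  valid molecule.
* ``SmilesTransformerGenerator`` -- standard sequence transformer over
  SMILES tokens with sinusoidal positional encodings.
* ``SmilesLstmGenerator`` -- 3-layer LSTM encoder-decoder; with
  ``attention=False`` the encoder's final hidden state initializes the
  decoder (LSTM-BASE), with ``attention=True`` each decoder step consumes
  an attention-weighted sum of encoder outputs concatenated with the token
  embedding (LSTM+ATTN).

They are sklearn-style estimators: hyperparameters in ``__init__``,
``fit(pairs, valid_pairs=None)`` minimizing token-level negative log
likelihood with Adam and patience-based early stopping, fitted state in
trailing-underscore attributes, and ``sample(scaffolds, k, seed)`` for
generation.
"""
from __future__ import annotations

import json
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .nn import Tensor
from .fragmenter import ScaffoldPair
from .graph_codec import (
    BLANK_IDX,
    END_IDX,
    GO_IDX,
    EncodeError,
    GraphMatrix,
    GraphState,
    GraphVocab,
    N_BOND_TYPES,
    decode_graph,
    encode_graph,
    state_from_scaffold,
)
from .chem_io import MoleculeRecord
from .smiles_codec import SmilesVocab, encode_pair_table

logger = logging.getLogger("molgrow")

GENERATOR_KINDS = ("graph-transformer", "seq-transformer", "lstm-base", "lstm-attn")


def _multinomial(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise multinomial draw from a (B, V) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    u = rng.random((probs.shape[0], 1))
    return (u > cum).sum(axis=1).astype(np.int64)


def _mask_logits(logits: np.ndarray, allowed: list[set[int]]) -> np.ndarray:
    out = np.full_like(logits, -1e9)
    for b, al in enumerate(allowed):
        for a in al:
            out[b, a] = logits[b, a]
    return out


class _TrainLoopMixin:
    """Shared Adam/early-stopping loop over subclass-provided batches."""

    def _run_training(self, net, train_data, valid_data, rng):
        opt = nn.Adam(net.parameters(), lr=self.lr, clip_norm=5.0)
        n_train = self._data_size(train_data)
        best_loss, best_state, best_epoch = np.inf, None, 0
        trace = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n_train)
            tot, cnt = 0.0, 0.0
            for start in range(0, n_train, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, n_tok = self._batch_loss(net, train_data, idx)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                if opt.grads_finite():
                    opt.step()
                tot += float(loss.data) * n_tok
                cnt += n_tok
            train_nll = tot / cnt
            if valid_data is not None:
                with nn.no_grad():
                    valid_nll = self._eval_nll(net, valid_data)
            else:
                valid_nll = train_nll
            trace.append({"epoch": epoch, "train_nll": train_nll, "valid_nll": valid_nll})
            if valid_nll < best_loss - 1e-6:
                best_loss, best_epoch = valid_nll, epoch
                best_state = net.state_dict()
            if epoch - best_epoch >= self.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
        if best_state is not None:
            net.load_state_dict(best_state)
        return trace, best_epoch

    def _eval_nll(self, net, data):
        n = self._data_size(data)
        tot, cnt = 0.0, 0.0
        for start in range(0, n, self.batch_size):
            idx = np.arange(start, min(start + self.batch_size, n))
            loss, n_tok = self._batch_loss(net, data, idx)
            tot += float(loss.data) * n_tok
            cnt += n_tok
        return tot / cnt


# ---------------------------------------------------------------------------
# graph transformer


class _GraphNet(nn.Module):
    def __init__(self, n_atom_tokens, d_model, n_heads, n_layers, d_ff, l_max, rng):
        self.l_max = l_max
        self.d_model = d_model
        self.word_emb = nn.Embedding(n_atom_tokens * N_BOND_TYPES, d_model, rng)
        self.pe = nn.positional_encoding(np.arange(l_max * l_max), d_model)
        self.enc_layers = [
            nn.TransformerEncoderLayer(d_model, n_heads, d_ff, rng)
            for _ in range(n_layers)
        ]
        self.dec_layers = [
            nn.TransformerDecoderLayer(d_model, n_heads, d_ff, rng)
            for _ in range(n_layers)
        ]
        self.enc_norm = nn.LayerNorm(d_model)
        self.dec_norm = nn.LayerNorm(d_model)
        self.gru = nn.GRUCell(d_model, d_model, rng)
        self.atom_head = nn.Linear(d_model, n_atom_tokens, rng)
        self.bond_head = nn.Linear(d_model, N_BOND_TYPES, rng)
        self.conn_head = nn.Linear(d_model, l_max, rng)
        self.cur_head = nn.Linear(d_model, l_max, rng)
        self.atom_emb = nn.Embedding(n_atom_tokens, d_model, rng)
        self.bond_emb = nn.Embedding(N_BOND_TYPES, d_model, rng)
        self.conn_emb = nn.Embedding(l_max, d_model, rng)

    def embed_cols(self, cols: np.ndarray) -> Tensor:
        """cols (B, 5, L) -> (B, L, d_model): word embedding + position PE.

        Word index W = T_atom*4 + T_bond; position index
        P = I_atom*L_max + I_connected feeds the sinusoidal table.
        """
        w = cols[:, 0] * N_BOND_TYPES + cols[:, 1]
        p = cols[:, 3] * self.l_max + cols[:, 2]
        return self.word_emb(w) + Tensor(self.pe[p])

    def encode(self, enc_cols: np.ndarray):
        pad = (enc_cols[:, 0] == BLANK_IDX) & (enc_cols[:, 1] == 0)
        x = self.embed_cols(enc_cols)
        mask = nn.padding_mask(pad)
        for layer in self.enc_layers:
            x = layer(x, mask)
        return self.enc_norm(x), pad

    def decode_hidden(self, dec_in_cols: np.ndarray, memory, mem_pad):
        x = self.embed_cols(dec_in_cols)
        self_mask = nn.causal_mask(dec_in_cols.shape[2])
        cross_mask = nn.padding_mask(mem_pad)
        for layer in self.dec_layers:
            x = layer(x, memory, self_mask, cross_mask)
        return self.dec_norm(x)

    def decision_logits(self, h, atom_idx, bond_idx, conn_idx):
        """Four per-step decisions chained through the GRU cell.

        Teacher-forced: ``atom_idx``/``bond_idx``/``conn_idx`` are the true
        (or sampled) choices feeding the next decision state.
        """
        s0 = h
        atom_logits = self.atom_head(s0)
        s1 = self.gru(self.atom_emb(atom_idx), s0)
        bond_logits = self.bond_head(s1)
        s2 = self.gru(self.bond_emb(bond_idx), s1)
        conn_logits = self.conn_head(s2)
        s3 = self.gru(self.conn_emb(conn_idx), s2)
        cur_logits = self.cur_head(s3)
        return atom_logits, bond_logits, conn_logits, cur_logits


def _pad_cols(cols: np.ndarray, width: int) -> np.ndarray:
    out = np.zeros((5, width), dtype=np.int64)
    out[:, : cols.shape[1]] = cols[:, :width]
    return out


class GraphTransformerGenerator(_TrainLoopMixin, BaseEstimator):
    """Graph-matrix transformer with stepwise valence masking.

    Parameters mirror the usual transformer hyperparameters; ``l_max`` is
    both the maximum number of atom positions and the matrix width budget.
    """

    def __init__(
        self,
        d_model: int = 512,
        n_heads: int = 8,
        n_layers: int = 3,
        d_ff: Optional[int] = None,
        l_max: int = 80,
        lr: float = 1e-4,
        batch_size: int = 256,
        epochs: int = 20,
        patience: int = 100,
        seed: int = 0,
    ):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.l_max = l_max
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed

    kind = "graph-transformer"

    # -- data preparation ----------------------------------------------------
    def _encode_pairs(self, pairs: Sequence[ScaffoldPair]):
        enc_list, dec_list, kept = [], [], []
        dropped = 0
        for p in pairs:
            try:
                matrix = encode_graph(
                    MoleculeRecord(p.molecule_smiles), p.scaffold, self.vocab_
                )
            except EncodeError:
                dropped += 1
                continue
            if matrix.n_columns > 2 * self.l_max:
                dropped += 1
                continue
            enc_cols, dec_cols = matrix.split_sections()
            enc_list.append(enc_cols)
            dec_list.append(dec_cols)
            kept.append(p)
        if dropped:
            logger.info("graph codec dropped %d pairs", dropped)
        if not enc_list:
            raise ValueError("no encodable training pairs")
        w_enc = max(c.shape[1] for c in enc_list)
        w_dec = max(c.shape[1] for c in dec_list) + 1  # room for the GO shift
        enc = np.stack([_pad_cols(c, w_enc) for c in enc_list])
        dec = np.stack([_pad_cols(c, w_dec) for c in dec_list])
        return {"enc": enc, "dec": dec, "pairs": kept}

    @staticmethod
    def _data_size(data):
        return data["enc"].shape[0]

    def _batch_loss(self, net, data, idx):
        enc_cols = data["enc"][idx]
        dec_cols = data["dec"][idx]
        b, _, l_dec = dec_cols.shape
        go_col = np.zeros((b, 5, 1), dtype=np.int64)
        go_col[:, 0, 0] = GO_IDX
        dec_in = np.concatenate([go_col, dec_cols[:, :, :-1]], axis=2)
        # valid up to and including the second END column
        is_end = dec_cols[:, 0] == END_IDX
        n_prev_end = np.cumsum(is_end, axis=1) - is_end
        col_mask = (n_prev_end < 2) & ~(
            (dec_cols[:, 0] == BLANK_IDX) & (dec_cols[:, 1] == 0)
        )
        memory, mem_pad = net.encode(enc_cols)
        h = net.decode_hidden(dec_in, memory, mem_pad)
        a_lg, b_lg, c_lg, k_lg = net.decision_logits(
            h, dec_cols[:, 0], dec_cols[:, 1], dec_cols[:, 2]
        )
        losses = []
        for logits, target in (
            (a_lg, dec_cols[:, 0]),
            (b_lg, dec_cols[:, 1]),
            (c_lg, dec_cols[:, 2]),
            (k_lg, dec_cols[:, 3]),
        ):
            l, _ = nn.nll_loss(logits, target, col_mask)
            losses.append(l)
        loss = (losses[0] + losses[1] + losses[2] + losses[3]) * 0.25
        return loss, float(col_mask.sum()) * 4

    # -- estimator API -------------------------------------------------------
    def fit(self, pairs: Sequence[ScaffoldPair], valid_pairs=None):
        rng = np.random.default_rng(self.seed)
        self.vocab_ = GraphVocab()
        train_data = self._encode_pairs(pairs)
        valid_data = self._encode_pairs(valid_pairs) if valid_pairs else None
        d_ff = self.d_ff or 4 * self.d_model
        self.net_ = _GraphNet(
            len(self.vocab_), self.d_model, self.n_heads, self.n_layers,
            d_ff, self.l_max, rng,
        )
        self.loss_trace_, self.best_epoch_ = self._run_training(
            self.net_, train_data, valid_data, rng
        )
        return self

    def episode_logprob(self, matrices: Sequence[GraphMatrix]) -> Tensor:
        """Summed log-likelihood of each episode's matrix under the model."""
        enc_list, dec_list = [], []
        for m in matrices:
            e, d = m.split_sections()
            enc_list.append(e)
            dec_list.append(d)
        w_enc = max(c.shape[1] for c in enc_list)
        w_dec = max(c.shape[1] for c in dec_list) + 1
        enc = np.stack([_pad_cols(c, w_enc) for c in enc_list])
        dec = np.stack([_pad_cols(c, w_dec) for c in dec_list])
        go_col = np.zeros((enc.shape[0], 5, 1), dtype=np.int64)
        go_col[:, 0, 0] = GO_IDX
        dec_in = np.concatenate([go_col, dec[:, :, :-1]], axis=2)
        is_end = dec[:, 0] == END_IDX
        n_prev_end = np.cumsum(is_end, axis=1) - is_end
        col_mask = (n_prev_end < 2) & ~((dec[:, 0] == BLANK_IDX) & (dec[:, 1] == 0))
        memory, mem_pad = self.net_.encode(enc)
        h = self.net_.decode_hidden(dec_in, memory, mem_pad)
        logits = self.net_.decision_logits(h, dec[:, 0], dec[:, 1], dec[:, 2])
        mask_t = Tensor(col_mask.astype(np.float32))
        total = None
        for lg, target in zip(logits, (dec[:, 0], dec[:, 1], dec[:, 2], dec[:, 3])):
            lp = nn.gather_last(nn.log_softmax(lg, axis=-1), target)
            contrib = (lp * mask_t).sum(axis=1)
            total = contrib if total is None else total + contrib
        return total

    def sample(
        self,
        scaffolds: Sequence[str],
        k: int = 20,
        seed: int = 0,
        max_steps: Optional[int] = None,
        return_matrices: bool = False,
    ) -> pd.DataFrame:
        """Sample ``k`` molecules per scaffold under the valence mask.

        Every emitted matrix decodes to a valid molecule; if the linking
        phase cannot connect all components, the largest one is kept.
        """
        rng = np.random.default_rng(seed)
        rows = []
        with nn.no_grad():
            for scaffold in scaffolds:
                try:
                    batch = self._sample_scaffold(scaffold, k, rng, max_steps)
                except EncodeError:
                    logger.info("skipping unencodable scaffold %r", scaffold)
                    continue
                rows.extend(batch)
        df = pd.DataFrame(rows, columns=["scaffold", "smiles", "matrix"])
        if not return_matrices:
            df = df.drop(columns="matrix")
        return df

    def _sample_scaffold(self, scaffold, k, rng, max_steps):
        net = self.net_
        state0, enc_cols = state_from_scaffold(scaffold, self.vocab_, self.l_max)
        if enc_cols.shape[1] >= self.l_max:
            raise EncodeError(f"scaffold {scaffold!r} exceeds the matrix width")
        max_steps = max_steps or (2 * self.l_max - enc_cols.shape[1])
        states = []
        for _ in range(k):
            st = GraphState(self.vocab_, self.l_max)
            for col in range(enc_cols.shape[1]):
                if enc_cols[0, col] == GO_IDX:
                    continue
                st.apply(enc_cols[:4, col], frag_label=int(enc_cols[4, col]))
            states.append(st)
        enc_batch = np.repeat(enc_cols[None], k, axis=0)
        memory, mem_pad = net.encode(enc_batch)
        go_col = np.zeros((k, 5, 1), dtype=np.int64)
        go_col[:, 0, 0] = GO_IDX
        dec_in = go_col
        done = np.zeros(k, dtype=bool)
        for _ in range(max_steps):
            h_all = net.decode_hidden(dec_in, memory, mem_pad)
            h = h_all[:, -1, :]
            # decision 1: atom type
            a_logits = net.atom_head(h).data
            allowed = [st.allowed_atoms() if not d else {BLANK_IDX} for st, d in zip(states, done)]
            a_choice = _multinomial(rng, _softmax_np(_mask_logits(a_logits, allowed)))
            s1 = net.gru(net.atom_emb(a_choice), h)
            # decision 2: bond type
            b_logits = net.bond_head(s1).data
            allowed = [
                st.allowed_bonds(int(a)) if not d else {0}
                for st, a, d in zip(states, a_choice, done)
            ]
            b_choice = _multinomial(rng, _softmax_np(_mask_logits(b_logits, allowed)))
            s2 = net.gru(net.bond_emb(b_choice), s1)
            # decision 3: connected atom index
            c_logits = net.conn_head(s2).data
            allowed = []
            for st, a, b_, d in zip(states, a_choice, b_choice, done):
                al = st.allowed_connections(int(a), int(b_)) if not d else {0}
                allowed.append(al or {0})
            c_choice = _multinomial(rng, _softmax_np(_mask_logits(c_logits, allowed)))
            s3 = net.gru(net.conn_emb(c_choice), s2)
            # decision 4: current atom index
            k_logits = net.cur_head(s3).data
            allowed = []
            for st, a, b_, c, d in zip(states, a_choice, b_choice, c_choice, done):
                al = st.allowed_currents(int(a), int(b_), int(c)) if not d else {0}
                allowed.append(al or {0})
            k_choice = _multinomial(rng, _softmax_np(_mask_logits(k_logits, allowed)))
            cols = np.zeros((k, 5, 1), dtype=np.int64)
            for i, st in enumerate(states):
                if done[i]:
                    continue
                col = (int(a_choice[i]), int(b_choice[i]), int(c_choice[i]), int(k_choice[i]))
                st.apply(col)
                cols[i, :4, 0] = col
                if st.phase == st.DONE:
                    done[i] = True
            dec_in = np.concatenate([dec_in, cols], axis=2)
            if done.all():
                break
        rows = []
        for st in states:
            while st.phase != st.DONE:
                st.apply((END_IDX, 0, 0, 0))
            full = np.array(
                [(GO_IDX, 0, 0, 0, 0)] + st.columns, dtype=np.int64
            ).T
            matrix = GraphMatrix(full)
            smiles = decode_graph(matrix, self.vocab_).smiles
            if "." in smiles:  # keep the largest component
                smiles = max(smiles.split("."), key=len)
            rows.append((scaffold, smiles, matrix))
        return rows


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# SMILES sequence models


class _SeqTransformerNet(nn.Module):
    def __init__(self, n_vocab, d_model, n_heads, n_layers, d_ff, max_len, rng):
        self.tok_emb = nn.Embedding(n_vocab, d_model, rng)
        self.pe = nn.positional_encoding(np.arange(max_len), d_model)
        self.enc_layers = [
            nn.TransformerEncoderLayer(d_model, n_heads, d_ff, rng)
            for _ in range(n_layers)
        ]
        self.dec_layers = [
            nn.TransformerDecoderLayer(d_model, n_heads, d_ff, rng)
            for _ in range(n_layers)
        ]
        self.enc_norm = nn.LayerNorm(d_model)
        self.dec_norm = nn.LayerNorm(d_model)
        self.out = nn.Linear(d_model, n_vocab, rng)

    def _embed(self, idx):
        return self.tok_emb(idx) + Tensor(self.pe[: idx.shape[1]][None])

    def encode(self, x_idx, blank):
        pad = x_idx == blank
        x = self._embed(x_idx)
        mask = nn.padding_mask(pad)
        for layer in self.enc_layers:
            x = layer(x, mask)
        return self.enc_norm(x), pad

    def decode(self, y_in, memory, mem_pad):
        x = self._embed(y_in)
        self_mask = nn.causal_mask(y_in.shape[1])
        cross_mask = nn.padding_mask(mem_pad)
        for layer in self.dec_layers:
            x = layer(x, memory, self_mask, cross_mask)
        return self.out(self.dec_norm(x))


class _LstmNet(nn.Module):
    def __init__(self, n_vocab, d_emb, d_hidden, n_layers, attention, rng):
        self.attention = attention
        self.emb = nn.Embedding(n_vocab, d_emb, rng)
        self.encoder = nn.LSTM(d_emb, d_hidden, n_layers, rng)
        d_dec_in = d_emb + d_hidden if attention else d_emb
        self.dec_cells = [
            nn.LSTMCell(d_dec_in if i == 0 else d_hidden, d_hidden, rng)
            for i in range(n_layers)
        ]
        self.out = nn.Linear(d_hidden, n_vocab, rng)
        self.d_hidden = d_hidden

    def encode(self, x_idx, blank):
        pad = x_idx == blank
        outs, state = self.encoder(self.emb(x_idx))
        return outs, state, pad

    def dec_step(self, tok_idx, state, enc_outs, enc_pad, h_top):
        """One decoder step; returns (logits, new_state, new_h_top)."""
        inp = self.emb(tok_idx)
        if self.attention:
            scores = (enc_outs @ h_top.reshape(-1, self.d_hidden, 1)).reshape(
                enc_outs.shape[0], -1
            )
            scores = scores + Tensor(enc_pad.astype(np.float32) * -1e9)
            weights = nn.softmax(scores, axis=-1)
            ctx = (weights.reshape(weights.shape[0], 1, -1) @ enc_outs).reshape(
                enc_outs.shape[0], -1
            )
            inp = nn.concat([inp, ctx], axis=-1)
        new_state = []
        for cell, (h, c) in zip(self.dec_cells, state):
            h, c = cell(inp, h, c)
            new_state.append((h, c))
            inp = h
        return self.out(inp), new_state, inp


class _SmilesGeneratorBase(_TrainLoopMixin, BaseEstimator):
    """Shared fit/sample plumbing for the three SMILES-based models."""

    kind = "seq"

    def _prepare(self, pairs):
        xs, ys, kept = encode_pair_table(pairs, self.vocab_, self.max_len)
        return {"x": xs, "y": ys, "pairs": kept}

    @staticmethod
    def _data_size(data):
        return data["x"].shape[0]

    def fit(self, pairs: Sequence[ScaffoldPair], valid_pairs=None):
        rng = np.random.default_rng(self.seed)
        self.vocab_ = SmilesVocab.from_corpus(
            [p.scaffold for p in pairs] + [p.molecule_smiles for p in pairs]
        )
        train_data = self._prepare(pairs)
        valid_data = None
        if valid_pairs:
            try:
                valid_data = self._prepare(valid_pairs)
            except ValueError:
                valid_data = None
        self.net_ = self._build_net(rng)
        self.loss_trace_, self.best_epoch_ = self._run_training(
            self.net_, train_data, valid_data, rng
        )
        return self

    def _loss_from_logits(self, logits, targets):
        mask = targets != self.vocab_.blank
        loss, _ = nn.nll_loss(logits, targets, mask)
        return loss, float(mask.sum())

    def sample(self, scaffolds: Sequence[str], k: int = 20, seed: int = 0) -> pd.DataFrame:
        """Multinomial sampling of ``k`` raw token strings per scaffold.

        Sequence models carry no validity guarantee; unparsable SMILES are
        returned as-is and measured downstream.
        """
        rng = np.random.default_rng(seed)
        rows = []
        with nn.no_grad():
            for scaffold in scaffolds:
                try:
                    x = self.vocab_.encode(scaffold, self.max_len)
                except ValueError:
                    logger.info("skipping over-length scaffold %r", scaffold)
                    continue
                x_batch = np.repeat(x[None], k, axis=0)
                for s in self._sample_batch(x_batch, rng):
                    rows.append((scaffold, s))
        return pd.DataFrame(rows, columns=["scaffold", "smiles"])

    def token_mask(self) -> np.ndarray:
        """Additive mask barring control tokens from being sampled."""
        mask = np.zeros(len(self.vocab_), dtype=np.float32)
        mask[self.vocab_.blank] = -1e9
        mask[self.vocab_.go] = -1e9
        return mask


class SmilesTransformerGenerator(_SmilesGeneratorBase):
    """Sequence transformer over SMILES tokens (scaffold -> molecule)."""

    kind = "seq-transformer"

    def __init__(
        self,
        d_model: int = 512,
        n_heads: int = 8,
        n_layers: int = 3,
        d_ff: Optional[int] = None,
        max_len: int = 100,
        lr: float = 1e-4,
        batch_size: int = 256,
        epochs: int = 20,
        patience: int = 100,
        seed: int = 0,
    ):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.max_len = max_len
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed

    def _build_net(self, rng):
        return _SeqTransformerNet(
            len(self.vocab_), self.d_model, self.n_heads, self.n_layers,
            self.d_ff or 4 * self.d_model, self.max_len, rng,
        )

    def _batch_loss(self, net, data, idx):
        x, y = data["x"][idx], data["y"][idx]
        # y starts with GO: input y[:, :-1], predict y[:, 1:]
        memory, mem_pad = net.encode(x, self.vocab_.blank)
        logits = net.decode(y[:, :-1], memory, mem_pad)
        return self._loss_from_logits(logits, y[:, 1:])

    def episode_logprob(self, x: np.ndarray, y: np.ndarray) -> Tensor:
        y_in = y[:, :-1]
        targets = y[:, 1:]
        memory, mem_pad = self.net_.encode(x, self.vocab_.blank)
        logits = self.net_.decode(y_in, memory, mem_pad)
        mask = Tensor((targets != self.vocab_.blank).astype(np.float32))
        lp = nn.gather_last(nn.log_softmax(logits, axis=-1), targets)
        return (lp * mask).sum(axis=1)

    def _sample_batch(self, x_batch, rng):
        b = x_batch.shape[0]
        memory, mem_pad = self.net_.encode(x_batch, self.vocab_.blank)
        seq = np.full((b, 1), self.vocab_.go, dtype=np.int64)
        finished = np.zeros(b, dtype=bool)
        extra = self.token_mask()
        for _ in range(self.max_len - 1):
            logits = self.net_.decode(seq, memory, mem_pad).data[:, -1, :]
            probs = _softmax_np(logits + extra)
            nxt = _multinomial(rng, probs)
            nxt[finished] = self.vocab_.blank
            finished |= nxt == self.vocab_.end
            seq = np.concatenate([seq, nxt[:, None]], axis=1)
            if finished.all():
                break
        return [self.vocab_.decode(row) for row in seq]


class SmilesLstmGenerator(_SmilesGeneratorBase):
    """LSTM encoder-decoder over SMILES tokens.

    ``attention=False`` is the plain model whose encoder final states seed
    the decoder; ``attention=True`` adds per-step attention over encoder
    outputs, concatenated with the token embedding as decoder input.
    """

    def __init__(
        self,
        d_emb: int = 128,
        d_hidden: int = 512,
        n_layers: int = 3,
        attention: bool = False,
        max_len: int = 100,
        lr: float = 1e-4,
        batch_size: int = 256,
        epochs: int = 20,
        patience: int = 100,
        seed: int = 0,
    ):
        self.d_emb = d_emb
        self.d_hidden = d_hidden
        self.n_layers = n_layers
        self.attention = attention
        self.max_len = max_len
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed

    @property
    def kind(self):
        return "lstm-attn" if self.attention else "lstm-base"

    def _build_net(self, rng):
        return _LstmNet(
            len(self.vocab_), self.d_emb, self.d_hidden, self.n_layers,
            self.attention, rng,
        )

    def _teacher_logits(self, net, x, y):
        enc_outs, enc_state, enc_pad = net.encode(x, self.vocab_.blank)
        state = enc_state
        h_top = state[-1][0]
        logits_steps = []
        for t in range(y.shape[1] - 1):
            logits, state, h_top = net.dec_step(
                y[:, t], state, enc_outs, enc_pad, h_top
            )
            logits_steps.append(logits)
        return nn.stack(logits_steps, axis=1)

    def _batch_loss(self, net, data, idx):
        x, y = data["x"][idx], data["y"][idx]
        logits = self._teacher_logits(net, x, y)
        targets = y[:, 1:]
        mask = targets != self.vocab_.blank
        loss, _ = nn.nll_loss(logits, targets, mask)
        return loss, float(mask.sum())

    def episode_logprob(self, x: np.ndarray, y: np.ndarray) -> Tensor:
        logits = self._teacher_logits(self.net_, x, y)
        targets = y[:, 1:]
        mask = Tensor((targets != self.vocab_.blank).astype(np.float32))
        lp = nn.gather_last(nn.log_softmax(logits, axis=-1), targets)
        return (lp * mask).sum(axis=1)

    def _sample_batch(self, x_batch, rng):
        net = self.net_
        b = x_batch.shape[0]
        enc_outs, state, enc_pad = net.encode(x_batch, self.vocab_.blank)
        h_top = state[-1][0]
        tok = np.full(b, self.vocab_.go, dtype=np.int64)
        rows = [np.full((b,), self.vocab_.go, dtype=np.int64)]
        finished = np.zeros(b, dtype=bool)
        extra = self.token_mask()
        for _ in range(self.max_len - 1):
            logits, state, h_top = net.dec_step(tok, state, enc_outs, enc_pad, h_top)
            probs = _softmax_np(logits.data + extra)
            nxt = _multinomial(rng, probs)
            nxt[finished] = self.vocab_.blank
            finished |= nxt == self.vocab_.end
            rows.append(nxt)
            tok = nxt
            if finished.all():
                break
        seq = np.stack(rows, axis=1)
        return [self.vocab_.decode(row) for row in seq]


def make_generator(kind: str, **params):
    """Factory over the four architecture names."""
    if kind == "graph-transformer":
        return GraphTransformerGenerator(**params)
    if kind == "seq-transformer":
        return SmilesTransformerGenerator(**params)
    if kind == "lstm-base":
        return SmilesLstmGenerator(attention=False, **params)
    if kind == "lstm-attn":
        return SmilesLstmGenerator(attention=True, **params)
    raise ValueError(f"unknown generator kind {kind!r}; choose from {GENERATOR_KINDS}")


def save_checkpoint(gen, path) -> None:
    """Parameter snapshot + hyperparameters + vocabulary, one .npz file."""
    state = gen.net_.state_dict()
    vocab_tokens = (
        gen.vocab_.atom_tokens
        if isinstance(gen.vocab_, GraphVocab)
        else gen.vocab_.tokens
    )
    meta = json.dumps(
        {"kind": gen.kind, "params": gen.get_params(), "vocab": vocab_tokens}
    )
    np.savez(path, __meta__=np.array(meta), **state)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    params = dict(meta["params"])
    kind = meta["kind"]
    if kind.startswith("lstm"):
        params.pop("attention", None)
    gen = make_generator(kind, **params)
    if kind == "graph-transformer":
        gen.vocab_ = GraphVocab(list(meta["vocab"]))
        rng = np.random.default_rng(gen.seed)
        gen.net_ = _GraphNet(
            len(gen.vocab_), gen.d_model, gen.n_heads, gen.n_layers,
            gen.d_ff or 4 * gen.d_model, gen.l_max, rng,
        )
    else:
        gen.vocab_ = SmilesVocab(list(meta["vocab"]))
        gen.net_ = gen._build_net(np.random.default_rng(gen.seed))
    gen.net_.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    gen.loss_trace_, gen.best_epoch_ = [], 0
    return gen
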