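# tagqa

Multi-span extractive question answering as BIO sequence tagging.

Instead of predicting a single answer span per question–passage pair,
`tagqa` treats extractive QA as token classification: the question is
concatenated to the passage (`[CLS] question [SEP] passage [SEP]`), gold
answers are located in the passage by exact search and labeled with the
BIO scheme, and a tagging head over a pluggable contextual encoder
predicts a tag for every token.  Decoding converts tag runs back to
literal passage substrings via character offsets, aggregates candidates
over all passages of a question, and ranks them — producing a *variable*
number of answers per question with no probability threshold and no
answer-count cap.  This suits list-type questions, which dominate
biomedical QA.

## What is in the box

| module | purpose |
| --- | --- |
| `tagqa.corpus_io` | BioASQ-dialect and SQuAD v1 readers/writers, question–passage–answer sample construction (`i*j` single-span vs `i` sequence-tagging semantics, unmatchable passages filtered) |
| `tagqa.annotation` | answer localisation (longest-leftmost, cased/uncased), input packing with 512-token tail truncation, BIO label assignment with supervision masking (special tokens, question tokens and sub-word continuations are IGNOREd) |
| `tagqa.tagger` | linear / BiLSTM / BiLSTM-CRF tagging heads on a minimal NumPy autodiff engine; masked cross-entropy; exact CRF inference (forward algorithm, forward–backward marginals, Viterbi); Adam training loop with per-epoch reshuffling |
| `tagqa.decoding` | tag runs → character spans (orphan-I repair) → literal substrings; per-span confidences (softmax mean or CRF span marginal); per-question aggregation, dedup and ranking; a post-hoc threshold filter for baseline comparison |
| `tagqa.evaluation` | list-question macro P/R/F1 (one-to-one group matching), factoid MRR@k, answer-count histograms, number-in-question detection |
| `tagqa.synthetic` | deterministic corpora with pseudo-entity answers planted verbatim in distractor-laden passages, synonym groups, ground-truth spans and self-check (`plant_check`) |
| `tagqa.pipeline` | end-to-end orchestration including two-stage transfer schedules |

There is no deep-learning framework dependency: the tagging layers,
CRF and training loop are pure NumPy/SciPy, and the default encoder is a
small trainable hashed-embedding model with context-window features so
the entire method runs in seconds on one CPU.  Pretrained transformer
encoders can be plugged in behind `tagqa.tagger.EncoderContract`.

## CLI

```sh
# make a synthetic corpus in the BioASQ dialect
tagqa generate --questions 100 --answers 1:4 --seed 7 --output train.json
tagqa generate --questions 30 --answers 1:4 --seed 8 --output test.json

# expand into samples (single_span: i*j per question; seq_tag: i)
tagqa convert --input train.json --format bioasq --config seq_tag --output samples.json

# train, predict and score list questions
tagqa run --train train.json --test test.json --steps 500 \
          --learning-rate 0.05 --seed 1 --predictions preds.json

# score an existing submission-shaped predictions file
tagqa evaluate --predictions preds.json --gold test.json --type list
```

Training defaults (batch size 18, learning rate 5e-6 fine-tune / 5e-5
transfer, 512-token sequences, per-epoch shuffling) mirror the reference
configuration for transformer-scale encoders; the tiny default encoder
wants a larger rate, e.g. `--learning-rate 0.05`.

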