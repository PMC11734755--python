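Below are two JSON extraction payloads obtained from the same manuscript
by different routes. Merge them into one payload containing every distinct
activity exactly once. Two activities are the same when enzyme, acceptors,
donors and products all agree. Return a JSON object {"activities": [...]}.
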