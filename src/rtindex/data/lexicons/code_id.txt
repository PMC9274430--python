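# Code repository identifiers
re:https?://(?:www\.)?github\.com/[\w.-]+/[\w.-]+
re:https?://(?:www\.)?gitlab\.com/[\w.-]+/[\w.-]+
re:https?://bitbucket\.org/[\w.-]+/[\w.-]+
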