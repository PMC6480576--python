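"""Shared small-grid phantom parameter JSON for CLI tests."""

import json

SMALL_PARAMS_JSON = json.dumps({"grid_shape": [64, 64, 32]})
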