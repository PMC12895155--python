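{
  "key": "Pango",
  "version": "v4.3",
  "attachment_parent": "99900021",
  "concepts": [
    {
      "id": "B",
      "parents": []
    },
    {
      "id": "B.1",
      "parents": [
        "B"
      ]
    },
    {
      "id": "B.1.1.7",
      "parents": [
        "B.1"
      ]
    }
  ]
}
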