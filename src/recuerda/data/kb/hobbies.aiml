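<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="hobbies" description="pasatiempos preferidos del paciente">
    <category role="trigger">
      <pattern>PASATIEMPO</pattern>
      <template><random>
        <li>¡Los pasatiempos son lo mejor! ¿Es cierto que te encanta <get name="pasatiempo_favorito"/>?</li>
        <li>¿Qué pasatiempo disfrutas más en estos días?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ PASATIEMPO</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>PASATIEMPO _</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PASATIEMPO _</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>PASATIEMPOS</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PASATIEMPOS</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>PASATIEMPOS _</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PASATIEMPOS _</pattern>
      <template><srai>PASATIEMPO</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué divertido! ¿Con quién compartías <get name="pasatiempo_favorito"/>?</li>
        <li>¿Qué recuerdos te trae <get name="pasatiempo_favorito"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Está bien. ¿Qué te gusta hacer para divertirte?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Platicar de pasatiempos siempre es agradable. ¿Cuál disfrutas más?</li>
        <li>El tiempo libre es un regalo. ¿En qué lo disfrutabas?</li>
      </random></template>
    </category>
  </topic>
</aiml>
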