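<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="actors" description="actores y personajes de interés para el paciente">
    <category role="trigger">
      <pattern>ACTOR</pattern>
      <template><random>
        <li>¿Es verdad que admiras mucho a <get name="actor_favorito"/>?</li>
        <li>¿Qué actor o actriz te parece estupendo?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ ACTOR</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>ACTOR _</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ACTOR _</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>ACTRIZ</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ACTRIZ</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>ACTRIZ _</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ACTRIZ _</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>ACTORES</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ACTORES</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>ACTORES _</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ ACTORES _</pattern>
      <template><srai>ACTOR</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Tiene mucho talento! ¿En qué película viste a <get name="actor_favorito"/>?</li>
        <li>¿Qué es lo que más admiras de <get name="actor_favorito"/>?</li>
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
      <template>Gracias por contarme. ¿Qué artista te gusta más?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Los artistas dejan huella. ¿De cuál te gustaría platicar?</li>
        <li>Hay actuaciones inolvidables. ¿Cuál recuerdas tú?</li>
      </random></template>
    </category>
  </topic>
</aiml>
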